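"""Trait-driven functional-group assignment and group-level aggregation.

Seventeen group codes cover rotifers (by feeding habit), copepods and
cladocerans (by body-size class x feeding habit) and protozoans (by feeding
habit). Larvae and other taxa are excluded from group-level analysis, with
one exception: records flagged as nauplii join the small filter-feeder
group, matching their role as juvenile copepods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ClassificationError, ValidationError

#: the 17 assignable codes; EXCLUDED is bookkeeping, never a statistic input
GROUP_CODES = (
    "RF", "RC", "RP",
    "SCF", "SCC", "MCF", "MCC", "LCF", "LCC",
    "PP", "PA", "PB", "PD", "PF", "PS", "PR", "PN",
)
EXCLUDED = "EXCLUDED"

_ROTIFER_MAP = {"filter": "RF", "carnivore": "RC", "algivore": "RP"}
_PROTOZOAN_MAP = {
    "photosynthetic": "PP",
    "algivore": "PA",
    "bacterivore": "PB",
    "detritivore": "PD",
    "fungivore": "PF",
    "saprotroph": "PS",
    "raptor": "PR",
    "omnivore": "PN",
}
_COPEPOD_HABIT = {"filter": "CF", "carnivore": "CC"}

# boundary sizes (0.7, 1.5) fall in the middle class
SMALL_MAX = 0.7
LARGE_MIN = 1.5


def size_class(body_size_mm: float) -> str:
    """S/M/L body-size class for copepods and cladocerans."""
    if body_size_mm < SMALL_MAX:
        return "S"
    if body_size_mm > LARGE_MIN:
        return "L"
    return "M"


def assign_functional_group(trait: pd.Series) -> str:
    """Map one trait record to its functional-group code.

    Deterministic and total over valid records; combinations outside the
    published map (e.g. a bacterivorous rotifer) raise ClassificationError.
    """
    taxon = trait["taxon_class"]
    habit = trait.get("feeding_habit")
    notes = str(trait.get("notes", "") or "")
    if taxon == "rotifer":
        try:
            return _ROTIFER_MAP[habit]
        except KeyError:
            raise ClassificationError(
                f"no functional group for rotifer with habit '{habit}'"
            ) from None
    if taxon == "copepod_cladoceran":
        size = trait.get("body_size_mm")
        if size is None or (isinstance(size, float) and np.isnan(size)):
            raise ClassificationError(
                f"copepod_cladoceran '{trait.get('species_id')}' lacks body size"
            )
        try:
            suffix = _COPEPOD_HABIT[habit]
        except KeyError:
            raise ClassificationError(
                f"no functional group for copepod_cladoceran with habit '{habit}'"
            ) from None
        return size_class(float(size)) + suffix
    if taxon == "protozoan":
        try:
            return _PROTOZOAN_MAP[habit]
        except KeyError:
            raise ClassificationError(
                f"no functional group for protozoan with habit '{habit}'"
            ) from None
    if taxon == "larva":
        if "nauplius" in notes.lower():
            return "SCF"
        return EXCLUDED
    if taxon == "other":
        return EXCLUDED
    raise ClassificationError(f"unknown taxon_class '{taxon}'")


def assign_all(traits: pd.DataFrame) -> pd.Series:
    """Assign every species in a trait table; returns species_id -> code."""
    out = {sp: assign_functional_group(row) for sp, row in traits.iterrows()}
    return pd.Series(out, name="group").rename_axis("species_id")


@dataclass
class GroupMatrix:
    """Functional-group x sample matrix with the excluded mass kept aside.

    Conservation invariant: included column sums + excluded column sums
    equal the species-matrix column sums.
    """

    values: pd.DataFrame  # included groups x samples
    excluded: pd.Series  # per-sample mass of excluded species
    assignment: pd.Series  # species_id -> group code
    measure: str = "abundance"

    @property
    def empty_groups(self) -> list[str]:
        return list(self.values.index[(self.values == 0).all(axis=1)])


def aggregate_by_group(matrix: pd.DataFrame, traits: pd.DataFrame, measure: str = "abundance") -> GroupMatrix:
    """Sum species rows into functional-group rows.

    Every species in ``matrix`` must have a trait record. All-zero group
    rows are retained so downstream matrices keep a stable shape; they are
    reported via ``GroupMatrix.empty_groups``.
    """
    missing = matrix.index.difference(traits.index)
    if len(missing):
        raise ValidationError(
            f"species without trait record: {', '.join(map(str, sorted(missing)))}"
        )
    assignment = assign_all(traits.loc[matrix.index])
    groups = assignment.reindex(matrix.index)
    sums = matrix.groupby(groups).sum()
    present = [g for g in GROUP_CODES if g in sums.index]
    values = sums.reindex(present).fillna(0.0)
    values.index.name = "group"
    if EXCLUDED in sums.index:
        excluded = sums.loc[EXCLUDED]
    else:
        excluded = pd.Series(0.0, index=matrix.columns)
    excluded.name = EXCLUDED
    return GroupMatrix(values=values, excluded=excluded, assignment=assignment, measure=measure)


def relative_composition(
    gm: GroupMatrix,
    sample_meta: pd.DataFrame | None = None,
    by: str = "sample",
) -> pd.DataFrame:
    """Per-unit share of each included group in the included total.

    ``by='stratum_season'`` pools samples on their stratum/season metadata
    (requires ``sample_meta`` indexed by sample_id). All-zero units yield
    NaN shares and are left flagged rather than silently dropped.
    """
    vals = gm.values
    if by == "stratum_season":
        if sample_meta is None:
            raise ValidationError("stratum_season pooling requires sample metadata")
        meta = sample_meta.loc[vals.columns]
        keys = meta["stratum"].astype(str) + "/" + meta["season"].astype(str)
        vals = vals.T.groupby(keys.values).sum().T
    elif by != "sample":
        raise ValidationError(f"unknown composition unit: {by}")
    totals = vals.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = vals / totals
    shares[vals.columns[totals == 0]] = np.nan
    return shares
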