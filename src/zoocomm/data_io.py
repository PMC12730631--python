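"""Reading, validating and writing community and trait tables.

The community table is long (tidy): one row per (sample, species) with the
individual count ``n`` and the filtered volume ``v`` in cubic metres.
Species not listed for a sample are implicit zeros, so the matrix form is a
closed universe over all observed samples and species — presence/absence
statistics downstream rely on that.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

COMMUNITY_COLUMNS = ("sample_id", "stratum", "season", "species_id", "n", "v")
TRAIT_COLUMNS = ("species_id", "taxon_class", "body_size_mm", "feeding_habit")

TAXON_CLASSES = frozenset(
    {"rotifer", "copepod_cladoceran", "protozoan", "larva", "other"}
)
FEEDING_HABITS = frozenset(
    {
        "filter",
        "carnivore",
        "algivore",
        "bacterivore",
        "detritivore",
        "fungivore",
        "saprotroph",
        "raptor",
        "omnivore",
        "photosynthetic",
    }
)


@dataclass
class CommunityDataset:
    """Long-form survey records plus consistent species/sample indexes.

    ``records`` carries one row per observed (sample, species) pair;
    ``sample_index`` is indexed by sample_id with stratum/season columns;
    ``species_index`` is the ordered set of species ids.
    """

    records: pd.DataFrame
    sample_index: pd.DataFrame = field(init=False)
    species_index: pd.Index = field(init=False)

    def __post_init__(self) -> None:
        df = self.records
        if df.empty:
            raise ValidationError("no records: community dataset is empty")
        dup = df.duplicated(subset=["sample_id", "species_id"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise ValidationError(
                f"duplicate (sample, species) pair: ({row['sample_id']}, {row['species_id']})"
            )
        if (df["v"] <= 0).any():
            bad = df.index[df["v"] <= 0][0]
            raise ValidationError(f"filtered volume must be > 0 (row {bad})")
        if (df["n"] < 0).any():
            bad = df.index[df["n"] < 0][0]
            raise ValidationError(f"count must be >= 0 (row {bad})")
        meta = (
            df[["sample_id", "stratum", "season"]]
            .drop_duplicates("sample_id")
            .set_index("sample_id")
        )
        # a sample must not claim two strata or seasons
        check = df.groupby("sample_id")[["stratum", "season"]].nunique()
        if (check > 1).any().any():
            bad = check.index[(check > 1).any(axis=1)][0]
            raise ValidationError(f"sample {bad} has inconsistent stratum/season metadata")
        self.sample_index = meta
        self.species_index = pd.Index(
            pd.unique(df["species_id"]), name="species_id"
        )

    @property
    def n_samples(self) -> int:
        return len(self.sample_index)

    @property
    def n_species(self) -> int:
        return len(self.species_index)

    @property
    def has_biomass(self) -> bool:
        return "biomass" in self.records.columns and self.records["biomass"].notna().all()


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    if "\t" in head:
        return "\t"
    return ","


def read_community_table(path: str | Path, sep: str | None = None) -> CommunityDataset:
    """Read and validate a long-format community table (CSV or TSV).

    Required columns: sample_id, stratum, season, species_id, n, v.
    Optional column: biomass (wet weight, mg per cubic metre).
    """
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "species_id": str})
    missing = [c for c in COMMUNITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(missing)}")
    for col in ("n", "v"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0]) + 2  # header + 1-based
            raise ValidationError(f"non-numeric value in column '{col}' at file line {row}")
        df[col] = coerced
    if "biomass" in df.columns:
        df["biomass"] = pd.to_numeric(df["biomass"], errors="coerce")
    if df.empty:
        raise ValidationError("no records: file contains a header only")
    return CommunityDataset(records=df.reset_index(drop=True))


def read_trait_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a species trait table keyed by species_id.

    Copepod/cladoceran records must carry a body size; enums are closed.
    """
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"species_id": str})
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(missing)}")
    if "notes" not in df.columns:
        df["notes"] = ""
    df["notes"] = df["notes"].fillna("")
    return validate_traits(df)


def validate_traits(df: pd.DataFrame) -> pd.DataFrame:
    if df["species_id"].duplicated().any():
        dup = df.loc[df["species_id"].duplicated(), "species_id"].iloc[0]
        raise ValidationError(f"duplicate species_id in trait table: {dup}")
    bad_class = set(df["taxon_class"]) - TAXON_CLASSES
    if bad_class:
        raise ValidationError(f"unknown taxon_class value(s): {sorted(bad_class)}")
    bad_habit = set(df["feeding_habit"].dropna()) - FEEDING_HABITS
    if bad_habit:
        raise ValidationError(f"unknown feeding_habit value(s): {sorted(bad_habit)}")
    df = df.copy()
    df["body_size_mm"] = pd.to_numeric(df["body_size_mm"], errors="coerce")
    cop = df["taxon_class"] == "copepod_cladoceran"
    if df.loc[cop, "body_size_mm"].isna().any():
        sp = df.loc[cop & df["body_size_mm"].isna(), "species_id"].iloc[0]
        raise ValidationError(f"copepod_cladoceran species {sp} lacks body_size_mm")
    if (df["body_size_mm"].dropna() <= 0).any():
        raise ValidationError("body_size_mm must be > 0 where given")
    return df.set_index("species_id", drop=False)


def to_abundance(ds: CommunityDataset) -> pd.DataFrame:
    """Species x sample abundance matrix in individuals per cubic metre (n/v).

    Absent (sample, species) pairs are zeros, never missing.
    """
    rec = ds.records
    ab = rec["n"] / rec["v"]
    mat = (
        pd.DataFrame(
            {"species_id": rec["species_id"], "sample_id": rec["sample_id"], "ab": ab}
        )
        .pivot(index="species_id", columns="sample_id", values="ab")
        .reindex(index=ds.species_index, columns=ds.sample_index.index)
        .fillna(0.0)
    )
    return mat


def to_biomass(ds: CommunityDataset) -> pd.DataFrame:
    """Species x sample wet-weight biomass matrix (mg per cubic metre)."""
    if "biomass" not in ds.records.columns:
        raise ValidationError("dataset has no biomass column")
    rec = ds.records
    mat = (
        rec.pivot(index="species_id", columns="sample_id", values="biomass")
        .reindex(index=ds.species_index, columns=ds.sample_index.index)
        .fillna(0.0)
    )
    return mat


def write_results(result, path: str | Path, fmt: str = "delimited") -> None:
    """Write a result table (DataFrame/Series) or mapping to disk.

    Delimited output uses 6 significant digits; JSON is written with the
    same float handling so that write-then-read round-trips at stored
    precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        payload = result
        if isinstance(result, pd.DataFrame):
            payload = json.loads(result.to_json(orient="split", double_precision=10))
        elif isinstance(result, pd.Series):
            payload = json.loads(result.to_json(double_precision=10))
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)
        return
    if fmt != "delimited":
        raise ValidationError(f"unknown output format: {fmt}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    if isinstance(result, pd.Series):
        result = result.to_frame()
    if not isinstance(result, pd.DataFrame):
        raise ValidationError("delimited output requires a table")
    result.to_csv(path, sep=sep, float_format="%.6g")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def dataset_from_wide(matrix: pd.DataFrame, sample_meta: pd.DataFrame, volume: float = 1.0) -> CommunityDataset:
    """Convenience import of a wide species x sample count matrix.

    All samples share one filtered volume; per-sample volumes need the long
    format.
    """
    if volume <= 0:
        raise ValidationError("shared volume must be > 0")
    long = matrix.stack().rename("n").reset_index()
    long.columns = ["species_id", "sample_id", "n"]
    long = long[long["n"] > 0]
    long["v"] = volume
    long = long.merge(sample_meta, left_on="sample_id", right_index=True)
    return CommunityDataset(records=long.reset_index(drop=True))


def write_dataset(ds: CommunityDataset, path: str | Path) -> None:
    """Serialize a CommunityDataset back to the long CSV/TSV dialect it reads."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    cols = [c for c in ("sample_id", "stratum", "season", "species_id", "n", "v", "biomass") if c in ds.records.columns]
    ds.records[cols].to_csv(path, sep=sep, index=False, float_format="%.10g")
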