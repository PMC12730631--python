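"""Seeded generator of survey-like community datasets with known structure.

Scenarios model a multi-estuary, multi-season survey: per-taxon-class
species inventories, lognormal abundances with seasonal multipliers, an
optional single-species bloom pinned to a target relative share within one
stratum-season, and controllable pairwise presence/absence coupling whose
expected phi coefficient equals the configured strength (exact for the
default occupancy 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_io import CommunityDataset, validate_traits
from .errors import ValidationError
from .functional_groups import EXCLUDED, assign_all

DEFAULT_SPECIES_PLAN = {
    "rotifer": 19,
    "copepod": 19,
    "protozoan": 13,
    "other": 11,
    "cladoceran": 7,
}

# lognormal (mu, sigma) of per-sample counts, per plan class
DEFAULT_ABUNDANCE_MODEL = {
    "rotifer": (3.5, 0.8),
    "copepod": (3.8, 0.9),
    "protozoan": (4.2, 1.0),
    "other": (2.5, 0.7),
    "cladoceran": (3.0, 0.8),
}

_ROTIFER_HABITS = ("filter", "carnivore", "algivore")
_COPEPOD_SIZES = (0.4, 1.0, 2.0)  # one per size class, jittered
_PROTOZOAN_HABITS = ("photosynthetic", "bacterivore", "algivore", "fungivore")
_WET_WEIGHT_MG = {
    "rotifer": 0.002,
    "copepod": 0.02,
    "protozoan": 0.0005,
    "other": 0.01,
    "cladoceran": 0.01,
}


@dataclass
class BloomSpec:
    stratum: str
    season: str
    target_share: float  # relative share within included groups
    species_id: str | None = None  # default: first photosynthetic protozoan

    def __post_init__(self) -> None:
        if not 0 < self.target_share < 1:
            raise ValidationError("bloom target share must be in (0, 1)")


@dataclass
class ScenarioConfig:
    strata: list[str] = field(default_factory=lambda: ["E1", "E2", "E3"])
    seasons: list[str] = field(default_factory=lambda: ["Mar", "Jun", "Sep", "Dec"])
    stations_per_stratum: int = 3
    species_plan: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SPECIES_PLAN))
    abundance_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ABUNDANCE_MODEL)
    )
    seasonal_multipliers: dict[str, float] | None = None
    bloom: BloomSpec | None = None
    association: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    occupancy: float = 0.5
    volume: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.strata or not self.seasons:
            raise ValidationError("need at least one stratum and one season")
        if self.stations_per_stratum < 1:
            raise ValidationError("stations_per_stratum must be >= 1")
        if sum(self.species_plan.values()) <= 0:
            raise ValidationError("species_plan must have a positive total")
        if any(v < 0 for v in self.species_plan.values()):
            raise ValidationError("species_plan counts must be >= 0")
        if not 0 < self.occupancy <= 1:
            raise ValidationError("occupancy must be in (0, 1]")
        if self.volume <= 0:
            raise ValidationError("volume must be > 0")
        for (_, _), rho in [(p, r) for p, r in self.association]:
            if abs(rho) > 1:
                raise ValidationError("association coupling strength must be in [-1, 1]")
        if self.seasonal_multipliers is None:
            # peak in the second season, trough in the last
            mults = [1.0] * len(self.seasons)
            if len(self.seasons) > 1:
                mults[1] = 3.0
            if len(self.seasons) > 3:
                mults[2], mults[3] = 1.5, 0.7
            self.seasonal_multipliers = dict(zip(self.seasons, mults))
        if set(self.seasonal_multipliers) != set(self.seasons):
            raise ValidationError("seasonal_multipliers must cover exactly the seasons")
        if self.bloom is not None:
            if self.bloom.stratum not in self.strata or self.bloom.season not in self.seasons:
                raise ValidationError("bloom stratum/season not in the scenario")

    @property
    def n_sites(self) -> int:
        return len(self.strata) * self.stations_per_stratum

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["association"] = [[[a, b], rho] for (a, b), rho in self.association]
        data["abundance_model"] = {k: list(v) for k, v in self.abundance_model.items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if data.get("bloom") is not None:
            data["bloom"] = BloomSpec(**data["bloom"])
        if data.get("association"):
            data["association"] = [
                ((a, b), float(rho)) for (a, b), rho in data["association"]
            ]
        data["abundance_model"] = {
            k: tuple(v) for k, v in data.get("abundance_model", DEFAULT_ABUNDANCE_MODEL).items()
        }
        return cls(**data)


def _species_ids(prefix: str, count: int) -> list[str]:
    return [f"{prefix}{i:02d}" for i in range(1, count + 1)]


def generate_traits(cfg: ScenarioConfig) -> pd.DataFrame:
    """Deterministic trait table covering all plan classes.

    Feeding habits and copepod body sizes cycle so that every size class
    and at least 11 functional groups are populated at the default plan.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    plan = cfg.species_plan
    for i, sp in enumerate(_species_ids("rot", plan.get("rotifer", 0))):
        rows.append(
            {"species_id": sp, "taxon_class": "rotifer", "body_size_mm": np.nan,
             "feeding_habit": _ROTIFER_HABITS[i % 2], "notes": "", "plan_class": "rotifer"}
        )
    for cls_name, prefix in (("copepod", "cop"), ("cladoceran", "cla")):
        for i, sp in enumerate(_species_ids(prefix, plan.get(cls_name, 0))):
            base = _COPEPOD_SIZES[i % 3]
            size = round(base * float(rng.uniform(0.85, 1.15)), 3)
            rows.append(
                {"species_id": sp, "taxon_class": "copepod_cladoceran",
                 "body_size_mm": size, "feeding_habit": ("filter", "carnivore")[i % 2],
                 "notes": "", "plan_class": cls_name}
            )
    for i, sp in enumerate(_species_ids("pro", plan.get("protozoan", 0))):
        rows.append(
            {"species_id": sp, "taxon_class": "protozoan", "body_size_mm": np.nan,
             "feeding_habit": _PROTOZOAN_HABITS[i % 4], "notes": "", "plan_class": "protozoan"}
        )
    n_other = plan.get("other", 0)
    for i, sp in enumerate(_species_ids("oth", n_other)):
        if i < 2 and n_other >= 2:
            rows.append(
                {"species_id": sp, "taxon_class": "larva", "body_size_mm": np.nan,
                 "feeding_habit": "filter", "notes": "nauplius", "plan_class": "other"}
            )
        elif i % 2 == 0:
            rows.append(
                {"species_id": sp, "taxon_class": "larva", "body_size_mm": np.nan,
                 "feeding_habit": "omnivore", "notes": "zoea", "plan_class": "other"}
            )
        else:
            rows.append(
                {"species_id": sp, "taxon_class": "other", "body_size_mm": np.nan,
                 "feeding_habit": "omnivore", "notes": "", "plan_class": "other"}
            )
    if not rows:
        raise ValidationError("species_plan produced no species")
    return validate_traits(pd.DataFrame(rows))


def _sample_ids(cfg: ScenarioConfig):
    out = []
    for stratum in cfg.strata:
        for season in cfg.seasons:
            for st in range(1, cfg.stations_per_stratum + 1):
                out.append((f"{stratum}-{season}-S{st}", stratum, season))
    return out


def generate_community(cfg: ScenarioConfig, traits: pd.DataFrame) -> CommunityDataset:
    """Draw a full survey dataset under the scenario.

    Presence is Bernoulli(occupancy) per species per sample; configured
    pairs share the leading species' draw with probability |rho| (or its
    complement for rho < 0), giving expected phi ~ rho at occupancy 0.5.
    Counts are lognormal scaled by the seasonal multiplier; the bloom
    species is rescaled afterwards so its share of the included
    (functional-group) total in the bloom stratum-season hits the target.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    species = list(traits.index)
    samples = _sample_ids(cfg)
    ns, nsp = len(samples), len(species)
    for (a, b), _ in cfg.association:
        if a not in traits.index or b not in traits.index:
            raise ValidationError(f"association pair ({a}, {b}) not in trait table")

    presence = (rng.random((nsp, ns)) < cfg.occupancy).astype(int)
    pres = pd.DataFrame(presence, index=species, columns=[s for s, _, _ in samples])
    for (a, b), rho in cfg.association:
        share = rng.random(ns) < abs(rho)
        row_a = pres.loc[a].to_numpy()
        row_b = pres.loc[b].to_numpy().copy()
        row_b[share] = row_a[share] if rho >= 0 else 1 - row_a[share]
        pres.loc[b] = row_b

    season_of = {sid: season for sid, _, season in samples}
    mult = np.array([cfg.seasonal_multipliers[season_of[sid]] for sid in pres.columns])
    plan_class = traits["plan_class"] if "plan_class" in traits.columns else pd.Series(
        "other", index=traits.index
    )
    mus = np.array([cfg.abundance_model.get(plan_class[sp], (3.0, 0.8))[0] for sp in species])
    sigmas = np.array([cfg.abundance_model.get(plan_class[sp], (3.0, 0.8))[1] for sp in species])
    raw = rng.lognormal(mean=mus[:, None], sigma=sigmas[:, None], size=(nsp, ns))
    counts = np.rint(raw * mult[None, :] * pres.to_numpy())
    counts = np.where((pres.to_numpy() == 1) & (counts < 1), 1, counts).astype(int)
    counts = pd.DataFrame(counts, index=species, columns=pres.columns)

    if cfg.bloom is not None:
        _apply_bloom(cfg, traits, counts, samples)

    weight = plan_class.map(_WET_WEIGHT_MG).astype(float)
    records = []
    for sid, stratum, season in samples:
        col = counts[sid]
        for sp in species:
            n = int(col[sp])
            if n == 0:
                continue
            records.append(
                {
                    "sample_id": sid,
                    "stratum": stratum,
                    "season": season,
                    "species_id": sp,
                    "n": n,
                    "v": cfg.volume,
                    "biomass": round(n / cfg.volume * weight[sp], 6),
                }
            )
    return CommunityDataset(records=pd.DataFrame(records))


def _apply_bloom(cfg: ScenarioConfig, traits: pd.DataFrame, counts: pd.DataFrame, samples) -> None:
    """Rescale the bloom species so its group-included share hits the target.

    Share is measured against the included (non-excluded) total of the bloom
    stratum-season, the same denominator relative_composition uses. The
    rescaling is solved per station, so the pooled share matches too.
    """
    bloom = cfg.bloom
    assignment = assign_all(traits)
    sp = bloom.species_id
    if sp is None:
        pp = [s for s in traits.index
              if traits.loc[s, "taxon_class"] == "protozoan"
              and traits.loc[s, "feeding_habit"] == "photosynthetic"]
        if not pp:
            raise ValidationError("bloom species unset and no photosynthetic protozoan available")
        sp = pp[0]
        bloom.species_id = sp
    if sp not in counts.index:
        raise ValidationError(f"bloom species {sp} not in community")
    included = assignment[assignment != EXCLUDED].index
    group = assignment[sp]
    co_members = [s for s in included if assignment[s] == group and s != sp]
    other_groups = [s for s in included if assignment[s] != group]
    t = bloom.target_share
    for sid, stratum, season in samples:
        if stratum != bloom.stratum or season != bloom.season:
            continue
        o = counts.loc[other_groups, sid].sum()
        g0 = counts.loc[co_members, sid].sum() if co_members else 0
        target = t / (1 - t) * o - g0
        counts.loc[sp, sid] = max(int(round(target)), 1)


def qinhuangdao_preset(seed: int = 0) -> ScenarioConfig:
    """Five strata x four seasons x three stations with one bloom stratum."""
    return ScenarioConfig(
        strata=["DHK", "YHK", "SHK", "THK", "LHK"],
        seasons=["Mar", "Jun", "Sep", "Dec"],
        stations_per_stratum=3,
        bloom=BloomSpec(stratum="THK", season="Sep", target_share=0.95),
        seed=seed,
    )
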