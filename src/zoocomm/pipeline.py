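"""End-to-end orchestration: ingest or simulate, then run every stage.

Stage order: group assignment -> diversity + dominance -> Bray-Curtis ->
niche breadth/overlap -> overall variance ratio -> pairwise phi network +
stability -> composition percentages. Each stage writes its own table so
the report layer never recomputes anything.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, community_metrics, data_io, functional_groups, niche
from .data_io import CommunityDataset, write_results, _json_default
from .errors import UndefinedStatisticError, ValidationError
from .synthetic_data import ScenarioConfig, generate_community, generate_traits

log = logging.getLogger("zoocomm")


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(f"stage '{name}' failed: {exc}") from exc


@dataclass
class RunConfig:
    community_path: str | None = None
    traits_path: str | None = None
    scenario: ScenarioConfig | None = None
    out_dir: str = "zoocomm_out"
    level: str = "group"  # species | group
    measure: str = "abundance"  # abundance | biomass
    dominance_threshold: float = 0.02
    overlap_threshold: float = 0.7
    strong_r: float = 0.7
    alpha: float = 0.05
    strata: list[str] | None = None
    seasons: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.community_path is not None and self.traits_path is not None
        if has_paths == (self.scenario is not None):
            raise ValidationError(
                "exactly one of (community+traits paths) or scenario must be given"
            )
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        for name in ("dominance_threshold", "overlap_threshold", "strong_r"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.level not in ("species", "group"):
            raise ValidationError("level must be 'species' or 'group'")
        if self.measure not in ("abundance", "biomass"):
            raise ValidationError("measure must be 'abundance' or 'biomass'")


def _load(cfg: RunConfig) -> tuple[CommunityDataset, pd.DataFrame]:
    if cfg.scenario is not None:
        traits = generate_traits(cfg.scenario)
        ds = generate_community(cfg.scenario, traits)
        return ds, traits
    ds = data_io.read_community_table(cfg.community_path)
    traits = data_io.read_trait_table(cfg.traits_path)
    return ds, traits


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write per-stage tables plus a JSON summary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run config: %s", asdict_config(cfg))

    with _stage("ingest"):
        ds, traits = _load(cfg)
    if cfg.strata:
        keep = ds.sample_index.index[ds.sample_index["stratum"].isin(cfg.strata)]
        ds = CommunityDataset(records=ds.records[ds.records["sample_id"].isin(keep)].reset_index(drop=True))
    if cfg.seasons:
        keep = ds.sample_index.index[ds.sample_index["season"].isin(cfg.seasons)]
        ds = CommunityDataset(records=ds.records[ds.records["sample_id"].isin(keep)].reset_index(drop=True))

    # deterministic sample/species ordering regardless of input row order
    ds = CommunityDataset(
        records=ds.records.sort_values(["sample_id", "species_id"]).reset_index(drop=True)
    )
    matrix = data_io.to_biomass(ds) if cfg.measure == "biomass" else data_io.to_abundance(ds)
    abundance = data_io.to_abundance(ds)

    with _stage("functional_groups"):
        gm = functional_groups.aggregate_by_group(matrix, traits, measure=cfg.measure)
        write_results(gm.assignment.to_frame(), out / "assignment.csv")
        write_results(gm.values, out / "group_matrix.csv")
        composition = functional_groups.relative_composition(
            gm, sample_meta=ds.sample_index, by="stratum_season"
        )
        write_results(composition, out / "group_composition.csv")

    with _stage("diversity_dominance"):
        pool = (
            ds.sample_index["stratum"].astype(str)
            + "/"
            + ds.sample_index["season"].astype(str)
        )
        diversity = community_metrics.diversity_table(abundance)
        diversity_pooled = community_metrics.diversity_table(abundance, pool=pool)
        write_results(diversity, out / "diversity_by_sample.csv")
        write_results(diversity_pooled, out / "diversity_by_stratum_season.csv")
        dom = community_metrics.dominance(abundance, threshold=cfg.dominance_threshold)
        write_results(dom, out / "dominance.csv")

    with _stage("bray_curtis"):
        pooled_groups = gm.values.T.groupby(pool.loc[gm.values.columns].values).sum().T
        bc = community_metrics.bray_curtis_matrix(pooled_groups)
        write_results(bc, out / "bray_curtis.csv")

    with _stage("niche"):
        entity_matrix = gm.values if cfg.level == "group" else matrix
        niche_res = niche.compute_niche(entity_matrix, threshold=cfg.overlap_threshold)
        write_results(niche_res.breadth.to_frame(), out / "niche_breadth.csv")
        write_results(niche_res.overlap, out / "niche_overlap.csv")
        write_results(niche_res.high_pairs, out / "niche_high_pairs.csv")

    with _stage("association"):
        pm = association.presence_absence(entity_matrix)
        try:
            overall = association.overall_variance_ratio(pm, alpha=cfg.alpha).to_dict()
        except UndefinedStatisticError as exc:
            overall = {"undefined": str(exc)}
        pairs = association.classify_pairs(pm, alpha=cfg.alpha)
        association.export_network(pairs, out / "association_edges.tsv")
        stability = association.stability_summary(pairs)
        pearson = association.pearson_pair_summary(entity_matrix, strong_r=cfg.strong_r)
        write_results(pearson["pairs"], out / "pearson_pairs.csv")

    with _stage("composition"):
        observed = traits.loc[traits.index.intersection(ds.species_index)]
        key = observed["plan_class"] if "plan_class" in observed.columns else observed["taxon_class"]
        class_counts = observed.groupby(key).size()
        comp_pct = community_metrics.composition_percentages(class_counts)
        write_results(comp_pct, out / "species_composition.csv")

    summary = {
        "config": asdict_config(cfg),
        "n_species": ds.n_species,
        "n_samples": ds.n_samples,
        "n_groups": int(len(gm.values.index)),
        "dominant_species": list(dom.index[dom["is_dominant"]]),
        "overall_association": overall,
        "stability": stability,
        "pearson": {
            "positive": pearson["positive"],
            "negative": pearson["negative"],
            "strong": pearson["strong"],
            "strong_r": pearson["strong_r"],
        },
        "high_overlap_pairs": int(len(niche_res.high_pairs)),
        "species_composition_percent": comp_pct["percent"].to_dict(),
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    return summary


def asdict_config(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d
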