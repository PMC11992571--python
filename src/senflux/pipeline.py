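"""Workflow orchestration: per-study runs, meta-analysis, time series.

Three workflows tie the stages together:

* **case–control study** — per-sample constrained flux profiles →
  differential flux (moderated two-group model) → DA pathway scores →
  all-against-all gene/metabolite knockouts scored against the study's
  flux shifts;
* **meta** — fixed-effects combination of the per-study differential
  tables, meta-level DA, and Stouffer-combined effective scores;
* **time series** — OLS slopes of flux on passage, per-passage-contrast
  DA trajectory against the first passage, slope-signed effective
  scores, and the biomass-vs-passage Spearman correlation (computed on
  per-passage means).

Knockout scans run on a per-study *reference model*: the model
constrained by the mean expression of the study's proliferative (or
first-passage) samples — perturbations are scored against the
unperturbed baseline state.

All randomness flows from a single root seed; each randomised stage
uses ``root_seed + <fixed stage offset>`` so partial re-runs are stable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import knockout as ko
from .constraints import (
    ExpressionProfile,
    KineticTable,
    MediumSpec,
    read_expression_tsv,
)
from .diffflux import DiffResult, case_control_diff, spearman_trajectory, timeseries_diff
from .metaflux import MetaResult, meta_table
from .network import MetabolicModel, load_model, split_reversible
from .pathway import PathwayDAResult, da_score, diff_da, meta_da
from .solver import constrained_sample_model, flux_profile, profile_from_model

logger = logging.getLogger(__name__)

#: fixed per-stage seed offsets (documented so partial re-runs are stable)
STAGE_SEED_OFFSETS = {
    "expression": 0,
    "study_da": 101,
    "meta_da": 202,
    "trajectory_da": 303,
}


def stage_seed(root: int, stage: str) -> int:
    return int(root) + STAGE_SEED_OFFSETS[stage]


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for a pipeline run.

    The effective config is persisted as JSON next to every run's
    outputs so a run can be reproduced from its artifact directory.
    """

    model_path: str = ""
    expression_path: str = ""
    metadata_path: str = ""
    kinetics_path: str = ""
    medium_path: str = ""
    out_dir: str = "senflux_out"
    fdr_threshold: float = 0.05
    p_threshold: float = 0.05
    lfc_threshold: float = 0.5
    maintenance_fraction: float = 0.9
    bootstrap_iterations: int = 1000
    min_subsystem_size: int = 3
    sigma: float = 1.0
    moderated: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fdr_threshold < 1 or not 0 < self.p_threshold < 1:
            raise ValueError("FDR and p thresholds must lie in (0, 1)")
        if not 0 <= self.maintenance_fraction <= 1:
            raise ValueError("maintenance fraction must lie in [0, 1]")
        if self.lfc_threshold <= 0:
            raise ValueError("lfc threshold must be > 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def load_inputs(config: RunConfig):
    model = load_model(config.model_path)
    exprs = read_expression_tsv(config.expression_path, config.metadata_path)
    kinetics = KineticTable.read_tsv(config.kinetics_path, sigma=config.sigma)
    medium = MediumSpec.read_tsv(config.medium_path)
    return model, exprs, kinetics, medium


# ---------------------------------------------------------------------------
# Stage drivers (in-memory)
# ---------------------------------------------------------------------------


def study_flux_matrix(
    model: MetabolicModel,
    exprs: list[ExpressionProfile],
    kinetics: KineticTable,
    medium: MediumSpec,
    fraction: float = 0.9,
) -> pd.DataFrame:
    """Reactions × samples matrix of FVA-midpoint fluxes."""
    profiles = [
        flux_profile(model, e, kinetics, medium, fraction=fraction) for e in exprs
    ]
    df = pd.DataFrame({p.sample_id: p.values for p in profiles})
    df.index.name = "reaction_id"
    return df


def reference_expression(exprs: list[ExpressionProfile]) -> ExpressionProfile:
    """Mean expression of the baseline samples of a study.

    Case–control studies: the proliferative group; time series: the
    first passage.
    """
    if any(e.group is not None for e in exprs):
        base = [e for e in exprs if e.group == "proliferative"]
    else:
        p0 = min(e.passage for e in exprs)
        base = [e for e in exprs if e.passage == p0]
    genes = sorted(base[0].values)
    values = {
        g: float(np.mean([b.values[g] for b in base])) for g in genes
    }
    return ExpressionProfile(
        sample_id=f"{base[0].study_id}_reference",
        study_id=base[0].study_id,
        values=values,
    )


def study_knockout_tables(
    model: MetabolicModel,
    exprs: list[ExpressionProfile],
    kinetics: KineticTable,
    medium: MediumSpec,
    diff: DiffResult,
    config: RunConfig,
):
    """Gene and metabolite KO matrices and scored tables for one study."""
    ref = reference_expression(exprs)
    ref_model, flags = constrained_sample_model(
        model, ref, kinetics, medium, fraction=config.maintenance_fraction
    )
    baseline = profile_from_model(ref_model, ref.sample_id, flags)
    gene_km = ko.gene_ko_matrix(ref_model, baseline, ref)
    met_km = ko.metabolite_ko_matrix(ref_model, baseline)
    tables = {}
    for km in (gene_km, met_km):
        est = ko.effective_scores(
            km, diff, p_thresh=config.p_threshold, lfc_thresh=config.lfc_threshold
        )
        tables[km.entity_kind] = ko.score_table_with_p(est)
        tables[km.entity_kind].table.attrs["study_id"] = diff.study_id
    return gene_km, met_km, tables["gene"], tables["metabolite"]


def analyze_study(
    model: MetabolicModel,
    exprs: list[ExpressionProfile],
    kinetics: KineticTable,
    medium: MediumSpec,
    config: RunConfig,
    knockouts: bool = True,
) -> dict:
    """Full case–control analysis of one study; returns a result bundle."""
    study_id = exprs[0].study_id
    t0 = time.time()
    fluxes = study_flux_matrix(
        model, exprs, kinetics, medium, fraction=config.maintenance_fraction
    )
    groups = {e.sample_id: e.group for e in exprs}
    diff = case_control_diff(
        fluxes, groups, study_id=study_id, moderated=config.moderated
    )
    subsystems = split_reversible(model).subsystems()
    da = diff_da(
        diff.table,
        subsystems,
        fdr_threshold=config.fdr_threshold,
        B=config.bootstrap_iterations,
        seed=stage_seed(config.seed, "study_da"),
        min_size=config.min_subsystem_size,
    )
    out = {"study_id": study_id, "fluxes": fluxes, "diff": diff, "da": da}
    if knockouts:
        gene_km, met_km, gene_scores, met_scores = study_knockout_tables(
            model, exprs, kinetics, medium, diff, config
        )
        out.update(
            gene_ko=gene_km,
            metabolite_ko=met_km,
            gene_scores=gene_scores,
            metabolite_scores=met_scores,
        )
    logger.info("study %s analysed in %.1fs", study_id, time.time() - t0)
    return out


def combine_studies(
    study_results: list[dict],
    model: MetabolicModel,
    config: RunConfig,
) -> dict:
    """Meta stage over per-study bundles (fixed-effects + DA + scores)."""
    diffs = [s["diff"] for s in study_results]
    meta = meta_table(diffs, fdr_threshold=config.fdr_threshold)
    subsystems = split_reversible(model).subsystems()
    mda = meta_da(
        meta,
        subsystems,
        fdr_threshold=config.fdr_threshold,
        B=config.bootstrap_iterations,
        seed=stage_seed(config.seed, "meta_da"),
        min_size=config.min_subsystem_size,
    )
    out = {"meta": meta, "meta_da": mda}
    if all("gene_scores" in s for s in study_results):
        out["gene_scores"] = ko.meta_scores([s["gene_scores"] for s in study_results])
        out["metabolite_scores"] = ko.meta_scores(
            [s["metabolite_scores"] for s in study_results]
        )
    return out


def analyze_timeseries(
    model: MetabolicModel,
    exprs: list[ExpressionProfile],
    kinetics: KineticTable,
    medium: MediumSpec,
    config: RunConfig,
    knockouts: bool = True,
) -> dict:
    """Time-series workflow: slopes, DA trajectory, KO scores, Spearman."""
    passages = {e.sample_id: e.passage for e in exprs}
    if len(set(passages.values())) < 3:
        raise ValueError("time-series analysis needs >= 3 distinct passages")
    fluxes = study_flux_matrix(
        model, exprs, kinetics, medium, fraction=config.maintenance_fraction
    )
    diff = timeseries_diff(fluxes, passages, study_id=exprs[0].study_id)
    subsystems = split_reversible(model).subsystems()
    da = diff_da(
        diff.table,
        subsystems,
        fdr_threshold=config.fdr_threshold,
        B=config.bootstrap_iterations,
        seed=stage_seed(config.seed, "study_da"),
        min_size=config.min_subsystem_size,
    )

    # trajectory: each passage contrasted against the first (case-control
    # style); the self-contrast of the first passage is zero by construction
    p0 = min(set(passages.values()))
    base_ids = [s for s, p in passages.items() if p == p0]
    traj_rows = []
    for pk in sorted(set(passages.values())):
        ids = [s for s, p in passages.items() if p == pk]
        sub = fluxes[base_ids + ids] if pk != p0 else fluxes[base_ids + base_ids]
        cols = list(sub.columns)
        renamed = sub.copy()
        renamed.columns = [f"c{i}" for i in range(len(cols))]
        grp = {
            f"c{i}": ("proliferative" if i < len(base_ids) else "senescent")
            for i in range(len(cols))
        }
        cdiff = case_control_diff(
            renamed, grp, study_id=f"p{pk}", moderated=config.moderated
        )
        sig = cdiff.table[cdiff.table["fdr"] < config.fdr_threshold]
        up = set(sig.index[sig["effect"] > 0])
        down = set(sig.index[sig["effect"] < 0])
        traj = da_score(up, down, subsystems, min_size=config.min_subsystem_size)
        for sub_name, row in traj.table.iterrows():
            traj_rows.append((pk, sub_name, row["da"], row["n_up"], row["n_down"],
                              row["n_total"]))
    trajectory = pd.DataFrame(
        traj_rows, columns=["passage", "subsystem", "da", "n_up", "n_down", "n_total"]
    )

    # biomass trajectory: Spearman of per-passage mean biomass vs passage
    biomass_id = split_reversible(model).objective_id
    biomass = fluxes.loc[biomass_id]
    per_passage = biomass.groupby(pd.Series(passages)).mean()
    rho, p = spearman_trajectory(per_passage.to_numpy(), per_passage.index.to_numpy())

    out = {
        "fluxes": fluxes,
        "diff": diff,
        "da": da,
        "trajectory": trajectory,
        "biomass_rho": rho,
        "biomass_rho_p": p,
        "biomass_per_passage": per_passage,
    }
    if knockouts:
        gene_km, met_km, gene_scores, met_scores = study_knockout_tables(
            model, exprs, kinetics, medium, diff, config
        )
        out.update(
            gene_ko=gene_km,
            metabolite_ko=met_km,
            gene_scores=gene_scores,
            metabolite_scores=met_scores,
        )
    return out


# ---------------------------------------------------------------------------
# Artifact-directory runners
# ---------------------------------------------------------------------------


def _write_manifest(out_dir: Path, files: list[str], config: RunConfig) -> None:
    manifest = {"files": sorted(files), "config": dataclasses.asdict(config)}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def group_by_study(exprs: list[ExpressionProfile]) -> dict[str, list[ExpressionProfile]]:
    studies: dict[str, list[ExpressionProfile]] = {}
    for e in exprs:
        studies.setdefault(e.study_id, []).append(e)
    return studies


def run_study(config: RunConfig, knockouts: bool = True) -> dict:
    """Run every study in the expression input; write per-study artifacts.

    Returns the per-study result bundles keyed by study id.
    """
    for attr in ("model_path", "expression_path", "metadata_path",
                 "kinetics_path", "medium_path"):
        path = getattr(config, attr)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"{attr} missing or not found: {path!r}")
    model, exprs, kinetics, medium = load_inputs(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    results = {}
    for study_id, study_exprs in sorted(group_by_study(exprs).items()):
        res = analyze_study(model, study_exprs, kinetics, medium, config,
                            knockouts=knockouts)
        results[study_id] = res
        prefix = out_dir / study_id
        res["fluxes"].to_csv(f"{prefix}_flux.tsv", sep="\t", float_format="%.10g")
        res["diff"].write_tsv(f"{prefix}_diff.tsv")
        res["da"].write_tsv(f"{prefix}_da.tsv")
        files += [f"{study_id}_flux.tsv", f"{study_id}_diff.tsv", f"{study_id}_da.tsv"]
        if knockouts:
            res["gene_ko"].write_tsv(f"{prefix}_gene_ko.tsv")
            res["metabolite_ko"].write_tsv(f"{prefix}_metabolite_ko.tsv")
            res["gene_scores"].write_tsv(f"{prefix}_gene_scores.tsv")
            res["metabolite_scores"].write_tsv(f"{prefix}_metabolite_scores.tsv")
            files += [
                f"{study_id}_gene_ko.tsv",
                f"{study_id}_metabolite_ko.tsv",
                f"{study_id}_gene_scores.tsv",
                f"{study_id}_metabolite_scores.tsv",
            ]
    config.to_json(out_dir / "config.json")
    _write_manifest(out_dir, files + ["config.json"], config)
    return results


def run_meta(config: RunConfig, study_results: dict) -> dict:
    """Meta stage over study bundles; writes meta artifacts."""
    if len(study_results) < 2:
        raise ValueError("meta-analysis needs >= 2 studies")
    model = load_model(config.model_path)
    combined = combine_studies(list(study_results.values()), model, config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    combined["meta"].write_tsv(out_dir / "meta_flux.tsv")
    combined["meta_da"].write_tsv(out_dir / "meta_da.tsv")
    if "gene_scores" in combined:
        combined["gene_scores"].write_tsv(out_dir / "meta_gene_scores.tsv")
        combined["metabolite_scores"].write_tsv(out_dir / "meta_metabolite_scores.tsv")
    return combined


def run_timeseries(config: RunConfig, knockouts: bool = True) -> dict:
    """Time-series workflow from config paths; writes artifacts."""
    model, exprs, kinetics, medium = load_inputs(config)
    res = analyze_timeseries(model, exprs, kinetics, medium, config,
                             knockouts=knockouts)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res["fluxes"].to_csv(out_dir / "ts_flux.tsv", sep="\t", float_format="%.10g")
    res["diff"].write_tsv(out_dir / "ts_diff.tsv")
    res["da"].write_tsv(out_dir / "ts_da.tsv")
    res["trajectory"].to_csv(out_dir / "ts_trajectory_da.tsv", sep="\t",
                             index=False, float_format="%.10g")
    with open(out_dir / "ts_biomass_spearman.json", "w") as fh:
        json.dump({"rho": res["biomass_rho"], "p": res["biomass_rho_p"]}, fh,
                  indent=1)
        fh.write("\n")
    if knockouts:
        res["gene_scores"].write_tsv(out_dir / "ts_gene_scores.tsv")
        res["metabolite_scores"].write_tsv(out_dir / "ts_metabolite_scores.tsv")
    config.to_json(out_dir / "config.json")
    return res
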