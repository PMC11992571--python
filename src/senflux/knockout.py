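"""All-against-all in-silico knockouts and effective-score target ranking.

A gene knockout zeroes the capacity of every reaction whose GPR rule
evaluates to 0 once the gene's abundance is set to 0 (isozymes survive
through the OR-sum); a metabolite knockout zeroes every reaction whose
stoichiometry involves the metabolite — including its exchanges, which
mirrors removing the species from the network.  After each deletion the
flux profile is recomputed under the same maintenance constraints as the
baseline (relaxing biomass, then ATP, if the deletion is lethal), and
the ternary effect on reaction j is ``sign(v_j^KO − v_j^baseline)``
with a zero threshold τ.  Transport reactions carry no enzymatic
constraint, so their columns are dropped from the effect matrices.

The gene (metabolite) effective score sums, over the significantly
changed fluxes, the product of the knockout effect sign and the flux
change sign:

    GES_i = Σ_j  G_ij^KO · sign(log2FC_j) · L_j,

with L_j = 1 iff p_j < 0.05 and |log2FC_j| > 0.5.  A positive score
means the deletion pushes fluxes the same way senescence does.  Entity
significance uses a norm-background p-value — a Normal fitted to all
entity scores of the run — and studies are combined by averaging scores
and a signed Stouffer combination of the per-study z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constraints import ExpressionProfile, enzyme_abundance
from .diffflux import DiffResult, bh_fdr
from .network import MetabolicModel, parse_gpr, evaluate_gpr
from .solver import FLUX_ZERO_TOL, FluxProfile, InfeasibleError, LinearProgram

_P_FLOOR = 1e-300


@dataclass
class KnockoutMatrix:
    """entities × reactions ternary effect matrix from single deletions."""

    entity_kind: str  # "gene" | "metabolite"
    effects: pd.DataFrame  # values in {-1, 0, +1}
    infeasible_flags: dict = field(default_factory=dict)

    @property
    def entities(self) -> list[str]:
        return list(self.effects.index)

    @property
    def reactions(self) -> list[str]:
        return list(self.effects.columns)

    def write_tsv(self, path) -> None:
        out = self.effects.astype(int).copy()
        out.index.name = f"{self.entity_kind}_id"
        out.to_csv(path, sep="\t")


@dataclass
class EffectiveScoreTable:
    """Per-entity effective scores with norm-background significance."""

    entity_kind: str
    table: pd.DataFrame  # index entity; cols score, p, fdr [+ per-study, meta_*]

    def top(self, n: int = 10) -> pd.DataFrame:
        col = "meta_score" if "meta_score" in self.table else "score"
        return self.table.sort_values(col, ascending=False).head(n)

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "kind", self.entity_kind)
        out.index.name = "entity_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Knockout scans
# ---------------------------------------------------------------------------


def _ko_midpoints(
    lp: LinearProgram,
    affected: list[str],
    model: MetabolicModel,
    report: list[str],
) -> tuple[pd.Series, dict]:
    """FVA midpoints after zeroing *affected* on a shared LP (bounds restored)."""
    saved = [(rid, lp.lb[lp.index[rid]], lp.ub[lp.index[rid]]) for rid in affected]
    maint = [
        (rid, lp.lb[lp.index[rid]])
        for rid in (model.objective_id, model.atp_demand_id)
        if rid and lp.lb[lp.index[rid]] > 0
    ]
    flags: dict = {}
    try:
        for rid in affected:
            lp.set_bounds(rid, 0.0, 0.0)
        # relax maintenance bounds (biomass first, then ATP) if lethal
        for key, rid in (("biomass", model.objective_id), ("atp", model.atp_demand_id)):
            try:
                lp.solve(model.objective_id, "max", vector=False)
                break
            except InfeasibleError:
                if rid and lp.lb[lp.index[rid]] > 0:
                    lp.set_bounds(rid, 0.0, lp.ub[lp.index[rid]])
                    flags[f"{key}_lb_relaxed"] = True
        vals = pd.Series(0.0, index=report)
        for rid in report:
            try:
                lo, _ = lp.solve(rid, "min", vector=False)
                hi, _ = lp.solve(rid, "max", vector=False)
                vals[rid] = (lo + hi) / 2.0
            except (InfeasibleError, RuntimeError):
                flags.setdefault("lp_failures", []).append(rid)
                vals[rid] = 0.0
        vals[vals.abs() < FLUX_ZERO_TOL] = 0.0
        return vals, flags
    finally:
        for rid, lb, ub in saved:
            lp.set_bounds(rid, lb, ub)
        for rid, lb in maint:
            lp.set_bounds(rid, lb, lp.ub[lp.index[rid]])


def _effects_from_scan(
    sample_model: MetabolicModel,
    baseline: FluxProfile,
    affected_map: dict[str, list[str]],
    entity_kind: str,
    tol: float = FLUX_ZERO_TOL,
) -> KnockoutMatrix:
    report = [r.id for r in sample_model.reactions if not r.is_transport]
    base = baseline.values.reindex(report).to_numpy()
    lp = LinearProgram(sample_model)
    entities = sorted(affected_map)
    effects = np.zeros((len(entities), len(report)), dtype=np.int8)
    flags: dict = {}
    for i, ent in enumerate(entities):
        affected = affected_map[ent]
        if not affected:
            continue
        vals, ko_flags = _ko_midpoints(lp, affected, sample_model, report)
        if ko_flags:
            flags[ent] = ko_flags
        delta = vals.to_numpy() - base
        effects[i] = np.where(delta > tol, 1, np.where(delta < -tol, -1, 0))
    return KnockoutMatrix(
        entity_kind=entity_kind,
        effects=pd.DataFrame(effects, index=entities, columns=report, dtype=int),
        infeasible_flags=flags,
    )


def gene_ko_matrix(
    sample_model: MetabolicModel,
    baseline: FluxProfile,
    expr: ExpressionProfile,
    genes: list[str] | None = None,
) -> KnockoutMatrix:
    """Single-gene deletion effects on every non-transport reaction.

    *sample_model* must be the same constrained (and maintained) model
    the baseline profile was computed on.
    """
    genes = list(genes if genes is not None else sample_model.genes)
    asts = {r.id: parse_gpr(r.gpr) for r in sample_model.reactions if r.gpr}
    base_ab = enzyme_abundance(sample_model, expr)
    affected_map: dict[str, list[str]] = {}
    for g in genes:
        values = dict(expr.values)
        values[g] = 0.0
        affected = [
            rid
            for rid, ast in asts.items()
            if base_ab[rid] > 0 and evaluate_gpr(ast, values) == 0
        ]
        affected_map[g] = affected
    return _effects_from_scan(sample_model, baseline, affected_map, "gene")


def metabolite_ko_matrix(
    sample_model: MetabolicModel,
    baseline: FluxProfile,
    metabolites: list[str] | None = None,
) -> KnockoutMatrix:
    """Single-metabolite deletion effects on every non-transport reaction.

    Deleting metabolite m zero-bounds every reaction (exchanges
    included) whose stoichiometry involves m.
    """
    mets = list(metabolites if metabolites is not None else sample_model.metabolite_ids)
    affected_map = {
        m: [r.id for r in sample_model.reactions if m in r.stoich] for m in mets
    }
    return _effects_from_scan(sample_model, baseline, affected_map, "metabolite")


# ---------------------------------------------------------------------------
# Effective scores
# ---------------------------------------------------------------------------


def effective_scores(
    ko: KnockoutMatrix,
    diff: DiffResult,
    p_thresh: float = 0.05,
    lfc_thresh: float = 0.5,
) -> EffectiveScoreTable:
    """GES/MES per entity: Σ_j effect_ij · sign(flux change_j) · L_j.

    For case–control studies ``L_j = 1`` iff ``p_j < p_thresh`` and
    ``|log2FC_j| > lfc_thresh``.  For time-series studies the slope sign
    substitutes for the fold-change sign and, because a per-passage
    slope has no natural magnitude scale, the selection rule is
    ``fdr_j < p_thresh`` (the rule used to call fluxes up/down with
    passage).  Scores are integers for ternary effects.
    """
    if not 0 < p_thresh < 1:
        raise ValueError("p_thresh must lie in (0, 1)")
    if lfc_thresh <= 0:
        raise ValueError("lfc_thresh must be > 0")
    missing = set(ko.reactions) - set(diff.table.index)
    if missing:
        raise ValueError(
            f"differential result does not cover knockout reactions: "
            f"{sorted(missing)[:5]}"
        )
    t = diff.table.loc[ko.reactions]
    if diff.kind == "timeseries":
        L = (t["fdr"] < p_thresh).to_numpy(float)
    else:
        L = ((t["p"] < p_thresh) & (t["effect"].abs() > lfc_thresh)).to_numpy(float)
    sign = np.sign(t["effect"].to_numpy())
    scores = ko.effects.to_numpy() @ (sign * L)
    table = pd.DataFrame({"score": scores}, index=ko.entities)
    return EffectiveScoreTable(entity_kind=ko.entity_kind, table=table)


def norm_background_p(scores, robust: bool = False) -> np.ndarray:
    """Two-sided p-values against a Normal fitted to all entity scores.

    ``robust=True`` uses median/MAD instead of mean/sd.  Requires at
    least 10 finite scores and a nondegenerate spread.
    """
    s = np.asarray(scores, dtype=float)
    if np.sum(np.isfinite(s)) < 10:
        raise ValueError("need >= 10 finite scores to fit a background")
    if robust:
        mu = float(np.median(s))
        sd = float(stats.median_abs_deviation(s, scale="normal"))
    else:
        mu = float(np.mean(s))
        sd = float(np.std(s, ddof=1))
    if sd == 0:
        raise ValueError("degenerate background: zero spread in scores")
    return np.clip(2.0 * stats.norm.sf(np.abs((s - mu) / sd)), _P_FLOOR, 1.0)


def score_table_with_p(
    est: EffectiveScoreTable, robust: bool = False
) -> EffectiveScoreTable:
    """Fill norm-background p and BH FDR into a score table."""
    table = est.table.copy()
    table["p"] = norm_background_p(table["score"].to_numpy(), robust=robust)
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    return EffectiveScoreTable(entity_kind=est.entity_kind, table=table)


def meta_scores(tables: list[EffectiveScoreTable]) -> EffectiveScoreTable:
    """Combine per-study effective scores across studies.

    meta_score is the arithmetic mean of the per-study scores; meta_p is
    a signed Stouffer combination, z_i = Φ⁻¹(1 − p_i/2)·sign(score_i),
    Z = Σ z_i / √k, over the studies where the entity is present.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 studies for a meta-analysis")
    kind = tables[0].entity_kind
    if any(t.entity_kind != kind for t in tables):
        raise ValueError("mixed entity kinds in meta_scores")
    scores = pd.DataFrame(
        {f"score_s{i}": t.table["score"] for i, t in enumerate(tables)}
    )
    pvals = pd.DataFrame({f"p_s{i}": t.table["p"] for i, t in enumerate(tables)})
    z = pd.DataFrame(index=scores.index)
    for i in range(len(tables)):
        p = np.clip(pvals[f"p_s{i}"].to_numpy(), _P_FLOOR, 1.0)
        z[f"z_s{i}"] = stats.norm.isf(p / 2.0) * np.sign(
            scores[f"score_s{i}"].to_numpy()
        )
    k = z.notna().sum(axis=1)
    Z = z.sum(axis=1, skipna=True) / np.sqrt(k.clip(lower=1))
    meta_p = np.clip(2.0 * stats.norm.sf(Z.abs()), _P_FLOOR, 1.0)
    table = scores.copy()
    table["meta_score"] = scores.mean(axis=1, skipna=True)
    table["meta_p"] = meta_p
    table["meta_fdr"] = bh_fdr(meta_p)
    return EffectiveScoreTable(entity_kind=kind, table=table)
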