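"""Fixed-effects meta-analysis of per-study differential flux results.

Per-study effects are combined with the classical inverse-variance
fixed-effects model (FEM): with standardized effects d_i and sampling
variances v_i, weights w_i = 1/v_i give

    d_bar = Σ w_i d_i / Σ w_i,    Z = d_bar · sqrt(Σ w_i),

and a two-sided normal p-value on Z.  For case–control studies the
standardized effect is a Hedges-g-like standardized mean difference
g_i = Δlog2 / s_pooled with sampling variance
v_i = (n1+n2)/(n1·n2) + g_i²/(2(n1+n2)); the small-sample J correction
is off by default.  For time-series studies d_i = beta_i/se_i with
v_i = 1 (a z-score).

A reaction is classified ``up`` when FDR < 0.05 and Z > 0, ``down`` when
FDR < 0.05 and Z < 0, ``ns`` otherwise.  The meta log2FC is the
arithmetic mean of the per-study log2FC values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffflux import DiffResult, bh_fdr

FDR_THRESHOLD = 0.05


@dataclass
class MetaResult:
    """Combined differential flux across the studies of one senescence type."""

    table: pd.DataFrame  # index reaction_id; cols meta_log2fc, z, p, fdr, n_studies, direction
    study_ids: list[str]

    @property
    def reactions(self) -> list[str]:
        return list(self.table.index)

    def significant_sets(self, fdr: float = FDR_THRESHOLD) -> tuple[set, set]:
        """(up, down) reaction id sets at the given FDR."""
        t = self.table
        up = set(t.index[(t["fdr"] < fdr) & (t["z"] > 0)])
        down = set(t.index[(t["fdr"] < fdr) & (t["z"] < 0)])
        return up, down

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "reaction_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def fem_combine(effects, variances) -> tuple[float, float]:
    """Inverse-variance fixed-effects combination of per-study effects.

    Returns ``(Z, p)`` with Z = d_bar·sqrt(Σ 1/v_i) and a two-sided
    normal p.  Requires every variance > 0 and at least one study.
    """
    d = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if d.size == 0:
        raise ValueError("no studies to combine")
    if np.any(v <= 0) or np.any(~np.isfinite(v)):
        raise ValueError("all study variances must be finite and > 0")
    w = 1.0 / v
    d_bar = float((w * d).sum() / w.sum())
    z = d_bar * np.sqrt(w.sum())
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def standardized_effects(diff: DiffResult, correction: bool = False) -> pd.DataFrame:
    """Per-reaction standardized effect and its sampling variance.

    Case–control: Hedges-g-like g = t·sqrt(1/n1+1/n2) with the usual
    SMD variance; ``correction=True`` applies the small-sample J factor.
    Time series: z = beta/se with unit variance.
    """
    t = diff.table
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(t["se"] > 0, t["effect"] / t["se"].replace(0, np.nan), 0.0)
    tval = np.nan_to_num(tval)
    if diff.kind == "case_control":
        n1, n2 = diff.n_case, diff.n_control
        g = tval * np.sqrt(1.0 / n1 + 1.0 / n2)
        if correction:
            df = n1 + n2 - 2
            g = g * (1.0 - 3.0 / (4.0 * df - 1.0))
        var = (n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2))
    else:
        g = tval
        var = np.ones_like(g)
    return pd.DataFrame({"d": g, "v": var}, index=t.index)


def meta_table(diffresults: list[DiffResult], fdr_threshold: float = FDR_THRESHOLD,
               correction: bool = False) -> MetaResult:
    """Combine per-study differential results into one meta table.

    Reactions are outer-joined across studies; a reaction observed in
    fewer than two studies is reported but classified ``ns`` and
    flagged via ``n_studies``.
    """
    if not diffresults:
        raise ValueError("no studies supplied")
    eff = {d.study_id or f"study{i}": standardized_effects(d, correction)
           for i, d in enumerate(diffresults)}
    lfc = pd.DataFrame({sid: d.table["effect"]
                        for sid, d in zip(eff, diffresults)})
    d_mat = pd.DataFrame({sid: e["d"] for sid, e in eff.items()})
    v_mat = pd.DataFrame({sid: e["v"] for sid, e in eff.items()})

    records = []
    for rid in d_mat.index:
        d_row = d_mat.loc[rid].dropna()
        v_row = v_mat.loc[rid].reindex(d_row.index)
        k = len(d_row)
        if k < 2:
            records.append((rid, float(lfc.loc[rid].mean()), 0.0, 1.0, k))
            continue
        z, p = fem_combine(d_row.to_numpy(), v_row.to_numpy())
        records.append((rid, float(lfc.loc[rid].mean()), z, p, k))
    table = pd.DataFrame(
        records, columns=["reaction_id", "meta_log2fc", "z", "p", "n_studies"]
    ).set_index("reaction_id")
    table["fdr"] = 1.0
    combined = table["n_studies"] >= 2
    if combined.any():
        table.loc[combined, "fdr"] = bh_fdr(table.loc[combined, "p"].to_numpy())
    direction = np.where(
        (table["fdr"] < fdr_threshold) & (table["z"] > 0) & combined,
        "up",
        np.where(
            (table["fdr"] < fdr_threshold) & (table["z"] < 0) & combined, "down", "ns"
        ),
    )
    table["direction"] = direction
    table = table[["meta_log2fc", "z", "p", "fdr", "n_studies", "direction"]]
    return MetaResult(table=table, study_ids=list(eff))
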