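"""Per-study differential flux statistics.

Case–control studies use a two-group linear model on ``log2(flux + ε)``
with empirical-Bayes variance moderation (pooled shrinkage of the
per-reaction variance toward the across-reaction mean with a prior
degrees-of-freedom d0, default 4 — the moderated-t behaviour familiar
from microarray-style pipelines); a plain t-test is available via
``moderated=False``.  The reported ``log2FC`` is
``log2((mean_case + ε)/(mean_control + ε))`` on the raw flux scale,
with ε a scale-free pseudocount (1e−6 × the global mean nonzero flux).

Time-series studies fit ordinary least squares ``flux ~ passage`` per
reaction; the slope's sign later substitutes for the fold-change sign
in the knockout effective scores.

Multiple testing is Benjamini–Hochberg throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EPS_SCALE = 1e-6  # pseudocount = EPS_SCALE * mean nonzero flux


@dataclass
class DiffResult:
    """Per-reaction differential result for one study.

    ``effect`` is log2FC for case–control or the per-passage slope beta
    for time series; ``se`` is its standard error on the scale the test
    was run on (log2 flux for case–control, raw flux for time series).
    """

    study_id: str
    table: pd.DataFrame  # index: reaction_id; cols: effect, se, p, fdr, mean_case, mean_control
    kind: str = "case_control"  # or "timeseries"
    n_case: int = 0
    n_control: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def reactions(self) -> list[str]:
        return list(self.table.index)

    def significant(self, fdr: float = 0.05):
        return self.table[self.table["fdr"] < fdr]

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "reaction_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pseudocount(fluxes: pd.DataFrame) -> float:
    nz = np.abs(fluxes.to_numpy())
    nz = nz[nz > 0]
    return EPS_SCALE * float(nz.mean()) if nz.size else EPS_SCALE


def case_control_diff(
    fluxes: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    study_id: str = "",
    moderated: bool = True,
    prior_df: float = 4.0,
) -> DiffResult:
    """Two-group differential flux for one study.

    Parameters
    ----------
    fluxes
        reactions × samples matrix of per-sample fluxes (FVA midpoints).
    groups
        sample id → ``"proliferative"`` | ``"senescent"``.

    Senescent is the case group: positive log2FC means higher flux in
    senescent samples.  Reactions that are exactly zero in every sample
    get log2FC 0 and p 1.
    """
    groups = pd.Series(groups)
    case_ids = groups.index[groups == "senescent"]
    ctrl_ids = groups.index[groups == "proliferative"]
    unknown = set(groups.index) - set(fluxes.columns)
    if unknown:
        raise ValueError(f"samples missing from flux matrix: {sorted(unknown)}")
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(case_ids)} senescent / "
            f"{len(ctrl_ids)} proliferative"
        )
    eps = _pseudocount(fluxes)
    case = fluxes[case_ids].to_numpy(dtype=float)
    ctrl = fluxes[ctrl_ids].to_numpy(dtype=float)
    n1, n2 = case.shape[1], ctrl.shape[1]

    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    log2fc = np.log2(mean_case + eps) - np.log2(mean_ctrl + eps)

    ylog_case = np.log2(case + eps)
    ylog_ctrl = np.log2(ctrl + eps)
    delta = ylog_case.mean(axis=1) - ylog_ctrl.mean(axis=1)
    df_resid = n1 + n2 - 2
    s2 = (
        ylog_case.var(axis=1, ddof=1) * (n1 - 1)
        + ylog_ctrl.var(axis=1, ddof=1) * (n2 - 1)
    ) / df_resid
    if moderated:
        s2_prior = float(np.mean(s2)) if np.mean(s2) > 0 else 0.0
        s2_post = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
        df_total = prior_df + df_resid
    else:
        s2_post = s2
        df_total = df_resid
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    constant = (np.abs(case).max(axis=1) == 0) & (np.abs(ctrl).max(axis=1) == 0)
    log2fc[constant] = 0.0
    p[constant] = 1.0
    se[constant] = 0.0
    p = np.clip(p, 0.0, 1.0)
    table = pd.DataFrame(
        {
            "effect": log2fc,
            "se": se,
            "p": p,
            "fdr": bh_fdr(p),
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
        },
        index=fluxes.index,
    )
    return DiffResult(
        study_id=study_id, table=table, kind="case_control", n_case=n1, n_control=n2
    )


def timeseries_diff(
    fluxes: pd.DataFrame,
    passages: dict[str, int] | pd.Series,
    study_id: str = "",
) -> DiffResult:
    """Per-reaction OLS slope of flux on passage number.

    ``effect`` is the raw-flux slope per passage; p is the two-sided
    t-test on the slope; FDR is Benjamini–Hochberg across reactions.
    """
    passages = pd.Series(passages).astype(float)
    x = passages.loc[[c for c in fluxes.columns if c in passages.index]]
    if x.nunique() < 3:
        raise ValueError("need >=3 distinct passage values")
    y = fluxes[x.index].to_numpy(dtype=float)
    xv = x.to_numpy(dtype=float)
    n = xv.size
    xc = xv - xv.mean()
    sxx = float((xc**2).sum())
    beta = (y * xc).sum(axis=1) / sxx
    alpha = y.mean(axis=1) - beta * xv.mean()
    resid = y - (alpha[:, None] + beta[:, None] * xv[None, :])
    df_resid = n - 2
    s2 = (resid**2).sum(axis=1) / df_resid
    se = np.sqrt(s2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), df_resid), 1.0)
    constant = np.ptp(y, axis=1) == 0
    p[constant] = 1.0
    table = pd.DataFrame(
        {
            "effect": beta,
            "se": se,
            "p": p,
            "fdr": bh_fdr(p),
            "mean_case": y.mean(axis=1),
            "mean_control": y.mean(axis=1),
        },
        index=fluxes.index,
    )
    return DiffResult(study_id=study_id, table=table, kind="timeseries", n_case=n)


def spearman_trajectory(values, covariate) -> tuple[float, float]:
    """Spearman rank correlation of a trajectory against a covariate.

    Ties get average ranks; the p-value is the t-approximation, which at
    small n is close to the exact permutation p.  Requires n >= 4.
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 observations")
    rho, p = stats.spearmanr(values, covariate)
    return float(rho), float(p)
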