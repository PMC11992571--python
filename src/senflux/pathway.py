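"""Differential-abundance (DA) pathway scores with a bootstrap null.

For pathway (subsystem) i the DA score is

    DA_i = (#significantly-up reactions − #significantly-down reactions)
           / (total reactions in subsystem i),

a value in [−1, 1]: +1 when every reaction of the pathway is
significantly up, −1 when every one is down.

Significance comes from a "bootstrap without replacement" null that
conditions on the observed totals: each iteration draws
``n_up + n_down`` reactions without replacement from the reaction
universe, splits the draw at random into an "up" set of size ``n_up``
and a "down" set of size ``n_down``, and recomputes every DA score.
Two-sided p-values use |DA| with the plus-one rule
``p = (1 + #{|DA_boot| >= |DA_obs|}) / (B + 1)``, so the smallest
attainable p is 1/(B+1).  Subsystems smaller than ``min_size`` (default
3) are reported with their DA but p = NaN — the resampling null is
degenerate below that size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffflux import bh_fdr
from .metaflux import MetaResult

MIN_SUBSYSTEM_SIZE = 3


@dataclass
class PathwayDAResult:
    """Per-subsystem DA scores; p/fdr filled by :func:`da_significance`."""

    table: pd.DataFrame  # index subsystem; cols da, n_up, n_down, n_total, p, fdr

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "subsystem"
        out.to_csv(path, sep="\t", float_format="%.10g")


def da_score(
    sig_up: set[str],
    sig_down: set[str],
    subsystems: dict[str, str],
    min_size: int = MIN_SUBSYSTEM_SIZE,
) -> PathwayDAResult:
    """DA scores for every subsystem of the reaction universe.

    *subsystems* maps every reaction of the universe to its pathway
    label; reactions with an empty label are ignored.  ``sig_up`` and
    ``sig_down`` must be disjoint subsets of the universe.
    """
    overlap = set(sig_up) & set(sig_down)
    if overlap:
        raise ValueError(f"up and down sets overlap: {sorted(overlap)[:5]}")
    stray = (set(sig_up) | set(sig_down)) - set(subsystems)
    if stray:
        raise ValueError(f"significant reactions outside universe: {sorted(stray)[:5]}")
    labels = sorted({s for s in subsystems.values() if s})
    rows = []
    for lab in labels:
        members = [r for r, s in subsystems.items() if s == lab]
        n_total = len(members)
        n_up = sum(1 for r in members if r in sig_up)
        n_down = sum(1 for r in members if r in sig_down)
        da = (n_up - n_down) / n_total
        rows.append((lab, da, n_up, n_down, n_total))
    table = pd.DataFrame(
        rows, columns=["subsystem", "da", "n_up", "n_down", "n_total"]
    ).set_index("subsystem")
    table["p"] = np.nan
    table["fdr"] = np.nan
    table.attrs["min_size"] = min_size
    return table.pipe(PathwayDAResult)


def da_significance(
    result: PathwayDAResult,
    subsystems: dict[str, str],
    n_up_total: int,
    n_down_total: int,
    B: int = 1000,
    seed: int = 0,
    min_size: int = MIN_SUBSYSTEM_SIZE,
) -> PathwayDAResult:
    """Fill bootstrap p-values and BH FDR into a DA result.

    The resampling is vectorised: one permutation of the universe per
    iteration, the first ``n_up_total`` drawn reactions labelled up and
    the next ``n_down_total`` labelled down.  Reproducible under *seed*.
    """
    if B < 100:
        raise ValueError("need B >= 100 bootstrap iterations")
    universe = sorted(subsystems)
    n = len(universe)
    n_draw = n_up_total + n_down_total
    if n_draw > n:
        raise ValueError(
            f"cannot draw {n_draw} significant reactions from universe of {n}"
        )
    labels = list(result.table.index)
    # subsystem membership indicator (subsystems × reactions)
    lab_index = {lab: i for i, lab in enumerate(labels)}
    member = np.zeros((len(labels), n), dtype=float)
    for j, rid in enumerate(universe):
        lab = subsystems[rid]
        if lab in lab_index:
            member[lab_index[lab], j] = 1.0
    n_total = member.sum(axis=1)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(labels))
    obs = np.abs(result.table["da"].to_numpy())
    for _ in range(B):
        perm = rng.permutation(n)
        up_ind = np.zeros(n)
        up_ind[perm[:n_up_total]] = 1.0
        down_ind = np.zeros(n)
        down_ind[perm[n_up_total:n_draw]] = 1.0
        da_boot = (member @ up_ind - member @ down_ind) / n_total
        exceed += np.abs(da_boot) >= obs - 1e-12
    p = (1.0 + exceed) / (B + 1.0)

    table = result.table.copy()
    eligible = table["n_total"].to_numpy() >= min_size
    table["p"] = np.where(eligible, p, np.nan)
    table["fdr"] = np.nan
    if eligible.any():
        table.loc[eligible, "fdr"] = bh_fdr(table.loc[eligible, "p"].to_numpy())
    return PathwayDAResult(table=table)


def diff_da(
    diff_table: pd.DataFrame,
    subsystems: dict[str, str],
    fdr_threshold: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    min_size: int = MIN_SUBSYSTEM_SIZE,
) -> PathwayDAResult:
    """Per-study DA: significant sets from one study's FDR column and signs."""
    sig = diff_table[diff_table["fdr"] < fdr_threshold]
    up = set(sig.index[sig["effect"] > 0])
    down = set(sig.index[sig["effect"] < 0])
    res = da_score(up, down, subsystems, min_size=min_size)
    return da_significance(
        res, subsystems, len(up), len(down), B=B, seed=seed, min_size=min_size
    )


def meta_da(
    meta: MetaResult,
    subsystems: dict[str, str],
    fdr_threshold: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    min_size: int = MIN_SUBSYSTEM_SIZE,
) -> PathwayDAResult:
    """Meta-level DA from the meta-analysis significant flux sets."""
    up, down = meta.significant_sets(fdr_threshold)
    res = da_score(up, down, subsystems, min_size=min_size)
    return da_significance(
        res, subsystems, len(up), len(down), B=B, seed=seed, min_size=min_size
    )
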