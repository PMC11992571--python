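"""Model/Results facade over the analysis pipeline.

`SenescenceFluxModel` is built from the data of an experiment — a
metabolic network, a genes × samples expression matrix with sample
metadata, a kinetic table and a medium — and `fit()` runs the workflow
the metadata implies (case–control studies with meta-analysis, or a
passage time series), returning a `SenescenceFluxResults` object that
carries the per-study and combined estimates, their uncertainties, and
a `summary()` table.

    >>> model = SenescenceFluxModel.from_directory("data/")
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .constraints import (
    ExpressionProfile,
    KineticTable,
    MediumSpec,
    read_expression_tsv,
)
from .network import MetabolicModel, load_model
from .pipeline import (
    RunConfig,
    analyze_study,
    analyze_timeseries,
    combine_studies,
    group_by_study,
)


class SenescenceFluxModel:
    """Expression-constrained metabolic flux analysis of senescence data.

    Parameters
    ----------
    network
        The stoichiometric model (with GPR rules and subsystems).
    expression
        Per-sample expression profiles (FPKM-like values).
    kinetics, medium
        Enzyme kcat table and exchange uptake limits.
    **config_kwargs
        Threshold/seed overrides forwarded to :class:`RunConfig`
        (``fdr_threshold``, ``bootstrap_iterations``, ``seed``, ...).
    """

    def __init__(
        self,
        network: MetabolicModel,
        expression: list[ExpressionProfile],
        kinetics: KineticTable,
        medium: MediumSpec,
        **config_kwargs,
    ):
        network.validate()
        if not expression:
            raise ValueError("no expression samples supplied")
        self.network = network
        self.expression = expression
        self.kinetics = kinetics
        self.medium = medium
        self.config = RunConfig(**config_kwargs)

    @classmethod
    def from_directory(cls, path, **config_kwargs) -> "SenescenceFluxModel":
        """Build from a directory holding ``model.json``, ``expression.tsv``,
        ``samples.tsv``, ``kinetics.tsv`` and ``medium.tsv``."""
        path = Path(path)
        return cls(
            network=load_model(path / "model.json"),
            expression=read_expression_tsv(
                path / "expression.tsv", path / "samples.tsv"
            ),
            kinetics=KineticTable.read_tsv(path / "kinetics.tsv"),
            medium=MediumSpec.read_tsv(path / "medium.tsv"),
            **config_kwargs,
        )

    @property
    def mode(self) -> str:
        return (
            "case_control"
            if any(e.group is not None for e in self.expression)
            else "timeseries"
        )

    def fit(self, knockouts: bool = True) -> "SenescenceFluxResults":
        """Run the full workflow; returns a results object."""
        if self.mode == "case_control":
            studies = {
                sid: analyze_study(
                    self.network, exprs, self.kinetics, self.medium, self.config,
                    knockouts=knockouts,
                )
                for sid, exprs in sorted(group_by_study(self.expression).items())
            }
            combined = (
                combine_studies(list(studies.values()), self.network, self.config)
                if len(studies) >= 2
                else {}
            )
            return SenescenceFluxResults(self, studies=studies, combined=combined)
        ts = analyze_timeseries(
            self.network, self.expression, self.kinetics, self.medium, self.config,
            knockouts=knockouts,
        )
        return SenescenceFluxResults(self, timeseries=ts)


class SenescenceFluxResults:
    """Fitted results: estimates, significance, and ranked targets.

    Attributes
    ----------
    studies : dict
        Per-study bundles (``fluxes``, ``diff``, ``da``, KO tables).
    meta_flux : DataFrame
        Combined per-reaction table (meta_log2fc, z, p, fdr, direction).
    pathway_da : DataFrame
        Meta-level DA scores per subsystem with bootstrap p / FDR.
    gene_scores, metabolite_scores : DataFrame
        Per-entity effective scores with meta p / FDR (case–control
        meta) or per-study scores (single study / time series).
    """

    def __init__(self, model: SenescenceFluxModel, studies=None, combined=None,
                 timeseries=None):
        self.model = model
        self.studies = studies or {}
        self.combined = combined or {}
        self.timeseries = timeseries or {}

    # -- flat accessors ---------------------------------------------------
    @property
    def meta_flux(self) -> pd.DataFrame | None:
        m = self.combined.get("meta")
        return m.table if m is not None else None

    @property
    def pathway_da(self) -> pd.DataFrame | None:
        source = self.combined.get("meta_da") or self.timeseries.get("da")
        return source.table if source is not None else None

    def _scores(self, kind: str) -> pd.DataFrame | None:
        key = f"{kind}_scores"
        src = self.combined.get(key) or self.timeseries.get(key)
        if src is None and len(self.studies) == 1:
            src = next(iter(self.studies.values())).get(key)
        return src.table if src is not None else None

    @property
    def gene_scores(self) -> pd.DataFrame | None:
        return self._scores("gene")

    @property
    def metabolite_scores(self) -> pd.DataFrame | None:
        return self._scores("metabolite")

    @property
    def biomass_rho(self) -> float | None:
        return self.timeseries.get("biomass_rho")

    def top_targets(self, kind: str = "gene", n: int = 10) -> pd.DataFrame:
        scores = self._scores(kind)
        if scores is None:
            raise ValueError("no knockout scores in this fit")
        col = "meta_score" if "meta_score" in scores else "score"
        return scores.sort_values(col, ascending=False).head(n)

    # -- summary ----------------------------------------------------------
    def summary(self, n_top: int = 8) -> str:
        lines = ["Senescence flux analysis", "=" * 24]
        if self.studies:
            lines.append(f"studies: {len(self.studies)} "
                         f"({', '.join(sorted(self.studies))})")
        if self.meta_flux is not None:
            up = int((self.meta_flux["direction"] == "up").sum())
            down = int((self.meta_flux["direction"] == "down").sum())
            lines.append(
                f"meta differential fluxes: {up} up, {down} down "
                f"(FDR < {self.model.config.fdr_threshold})"
            )
        if self.timeseries:
            diff = self.timeseries["diff"].table
            sig = diff[diff["fdr"] < self.model.config.fdr_threshold]
            lines.append(
                f"time-series fluxes: {int((sig['effect'] > 0).sum())} up, "
                f"{int((sig['effect'] < 0).sum())} down with passage"
            )
            lines.append(
                f"biomass vs passage: Spearman rho = {self.biomass_rho:.3f} "
                f"(p = {self.timeseries['biomass_rho_p']:.2g})"
            )
        if self.pathway_da is not None:
            da = self.pathway_da.dropna(subset=["p"]).sort_values("da")
            lines.append("")
            lines.append("pathway DA scores (most down-regulated first):")
            for sub, row in da.head(n_top).iterrows():
                lines.append(
                    f"  {sub:<14s} DA={row['da']:+.2f}  "
                    f"({int(row['n_up'])}u/{int(row['n_down'])}d of "
                    f"{int(row['n_total'])})  fdr={row['fdr']:.3g}"
                )
        for kind in ("gene", "metabolite"):
            scores = self._scores(kind)
            if scores is None:
                continue
            col = "meta_score" if "meta_score" in scores else "score"
            fdr_col = "meta_fdr" if "meta_fdr" in scores else "fdr"
            top = scores.sort_values(col, ascending=False).head(n_top)
            lines.append("")
            lines.append(f"top {kind} targets by effective score:")
            for ent, row in top.iterrows():
                fdr = row.get(fdr_col, np.nan)
                lines.append(f"  {ent:<14s} score={row[col]:+7.2f}  fdr={fdr:.3g}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        parts = [f"{len(self.studies)} studies"] if self.studies else []
        if self.timeseries:
            parts.append("timeseries")
        return f"<SenescenceFluxResults: {', '.join(parts) or 'empty'}>"
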