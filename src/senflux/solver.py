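"""LP machinery: FBA, maintenance constraints, FVA, per-sample flux profiles.

Flux balance analysis maximises an objective flux subject to steady-state
mass balance ``S·v = 0`` and box bounds on ``v``.  All LPs go through
:func:`scipy.optimize.linprog` with the HiGHS dual-simplex backend, which
is deterministic for fixed input, so repeated runs are bit-identical.

Maintenance constraints mirror the two-step rule used when building
per-sample models: first maximise the ATP demand flux and fix its lower
bound at 90 % of the optimum (ATP production is essential for any cell);
then maximise biomass under that constraint and fix its lower bound at
90 % of *its* optimum.  If either step is infeasible after a knockout,
the biomass bound is relaxed to 0 first, then the ATP bound, and the
relaxation is recorded — a lethal knockout must yield a defined flux
vector, not a crash.

The per-sample "flux" handed to the statistics is the FVA midpoint
``(min+max)/2`` (symmetric, robust to degenerate optimal vertices); the
FBA vertex is available via ``summary="fba_vertex"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .constraints import (
    ExpressionProfile,
    KineticTable,
    MediumSpec,
    build_sample_model,
)
from .network import MetabolicModel, split_reversible

#: absolute flux below which a value is treated as zero
FLUX_ZERO_TOL = 1e-6
#: fraction of the optimum used for maintenance lower bounds
MAINTENANCE_FRACTION = 0.9

_LINPROG_OPTS = {"presolve": True}

# scipy vendors the HiGHS bindings; a persistent solver instance lets FVA
# and knockout scans warm-start between objectives (large speedup).  The
# linprog code path below remains as a fallback.
try:  # pragma: no cover - import probe
    from scipy.optimize._highspy import _core as _hscore

    _HAVE_HIGHS_CORE = hasattr(_hscore, "_Highs")
except ImportError:  # pragma: no cover
    _hscore = None
    _HAVE_HIGHS_CORE = False


class InfeasibleError(RuntimeError):
    """The LP has no feasible point (explicit — never silent zeros)."""


@dataclass
class FluxProfile:
    """Per-sample reaction fluxes (FVA midpoints) with their FVA ranges."""

    sample_id: str
    values: pd.Series
    fva_min: pd.Series
    fva_max: pd.Series
    feasibility_flags: dict = field(default_factory=dict)

    @property
    def reactions(self) -> list[str]:
        return list(self.values.index)


class LinearProgram:
    """S·v = 0 with box bounds; repeated solves with varying objectives.

    Backed by a persistent HiGHS instance (dual simplex, single thread,
    deterministic) when scipy's vendored bindings are available, falling
    back to :func:`scipy.optimize.linprog` otherwise.  Both paths solve
    the identical LP.
    """

    def __init__(self, model: MetabolicModel, backend: str | None = None):
        self.reaction_ids = model.reaction_ids
        self.index = {r: i for i, r in enumerate(self.reaction_ids)}
        n_met = len(model.metabolites)
        met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(model.reactions):
            for met, coef in rxn.stoich.items():
                rows.append(met_index[met])
                cols.append(j)
                vals.append(coef)
        self.A = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(n_met, len(model.reactions))
        )
        self.lb = np.array([r.lb for r in model.reactions], dtype=float)
        self.ub = np.array([r.ub for r in model.reactions], dtype=float)
        if backend is None:
            backend = "highs" if _HAVE_HIGHS_CORE else "linprog"
        self.backend = backend
        self._h = self._build_highs() if backend == "highs" else None

    def _build_highs(self):
        n, m = len(self.reaction_ids), self.A.shape[0]
        csc = self.A.tocsc()
        lp = _hscore.HighsLp()
        lp.num_col_ = n
        lp.num_row_ = m
        lp.col_cost_ = np.zeros(n)
        lp.col_lower_ = self.lb.copy()
        lp.col_upper_ = self.ub.copy()
        lp.row_lower_ = np.zeros(m)
        lp.row_upper_ = np.zeros(m)
        lp.a_matrix_.format_ = _hscore.MatrixFormat.kColwise
        lp.a_matrix_.start_ = csc.indptr.astype(np.int32)
        lp.a_matrix_.index_ = csc.indices.astype(np.int32)
        lp.a_matrix_.value_ = csc.data.astype(float)
        h = _hscore._Highs()
        h.setOptionValue("output_flag", False)
        h.setOptionValue("solver", "simplex")
        h.setOptionValue("threads", 1)
        h.passModel(lp)
        return h

    def set_bounds(self, rid: str, lb: float, ub: float) -> None:
        j = self.index[rid]
        self.lb[j], self.ub[j] = lb, ub
        if self._h is not None:
            self._h.changeColBounds(j, lb, ub)

    def solve(self, objective: str, sense: str = "max", vector: bool = True):
        """Optimise a single reaction flux.

        Returns ``(optimum, flux vector)``; with ``vector=False`` the
        second element is ``None`` (cheaper for FVA-style scans).
        """
        if self._h is not None:
            return self._solve_highs(objective, sense, vector)
        return self._solve_linprog(objective, sense, vector)

    def _solve_highs(self, objective: str, sense: str, vector: bool):
        h = self._h
        j = self.index[objective]
        sign = -1.0 if sense == "max" else 1.0
        h.changeColCost(j, sign)
        h.run()
        status = h.getModelStatus()
        if status == _hscore.HighsModelStatus.kInfeasible:
            h.changeColCost(j, 0.0)
            raise InfeasibleError(f"LP infeasible while optimising {objective}")
        if status != _hscore.HighsModelStatus.kOptimal:
            h.changeColCost(j, 0.0)
            raise RuntimeError(f"LP failed for {objective}: status {status}")
        opt = sign * h.getInfo().objective_function_value
        x = None
        if vector:
            x = pd.Series(
                np.asarray(h.getSolution().col_value, dtype=float),
                index=self.reaction_ids,
            )
        h.changeColCost(j, 0.0)
        return opt, x

    def _solve_linprog(self, objective: str, sense: str, vector: bool):
        c = np.zeros(len(self.reaction_ids))
        c[self.index[objective]] = -1.0 if sense == "max" else 1.0
        res = linprog(
            c,
            A_eq=self.A,
            b_eq=np.zeros(self.A.shape[0]),
            bounds=np.column_stack([self.lb, self.ub]),
            method="highs-ds",
            options=_LINPROG_OPTS,
        )
        if res.status == 2:
            raise InfeasibleError(f"LP infeasible while optimising {objective}")
        if not res.success:
            raise RuntimeError(
                f"LP failed for {objective}: status {res.status} ({res.message})"
            )
        opt = -res.fun if sense == "max" else res.fun
        return opt, (pd.Series(res.x, index=self.reaction_ids) if vector else None)


def fba(model: MetabolicModel, objective_id: str | None = None):
    """Maximise *objective_id* (default: the model objective).

    Returns ``(optimum, flux vector)``; raises :class:`InfeasibleError`
    on an infeasible model.
    """
    lp = LinearProgram(model)
    return lp.solve(objective_id or model.objective_id, "max")


def apply_maintenance(
    model: MetabolicModel,
    fraction: float = MAINTENANCE_FRACTION,
    biomass_bound: bool = True,
) -> tuple[MetabolicModel, dict]:
    """Fix ATP-demand and biomass lower bounds at *fraction* of their optima.

    Sequential (lexicographic): ATP demand first, then biomass under the
    ATP constraint.  A zero optimum leaves the bound at 0 with a flag.
    Returns ``(constrained copy, flags)``.
    """
    out = model.copy()
    flags: dict = {}
    lp = LinearProgram(out)
    for rid, key, enabled in (
        (out.atp_demand_id, "atp", True),
        (out.objective_id, "biomass", biomass_bound),
    ):
        if not rid or not enabled:
            continue
        try:
            opt, _ = lp.solve(rid, "max")
        except InfeasibleError:
            flags[f"{key}_infeasible"] = True
            continue
        lb = fraction * opt
        if opt <= FLUX_ZERO_TOL:
            lb = 0.0
            flags[f"{key}_zero_optimum"] = True
        lp.set_bounds(rid, lb, out.reaction(rid).ub)
        out.reaction(rid).lb = lb
    return out, flags


def relax_maintenance(model: MetabolicModel) -> tuple[MetabolicModel, dict]:
    """Relax biomass then ATP maintenance bounds until the model is feasible.

    Used after knockouts: lethal deletions get a defined (relaxed) model
    with flags recording which bounds were dropped.
    """
    out = model
    flags: dict = {}
    for key, rid in (("biomass", model.objective_id), ("atp", model.atp_demand_id)):
        lp = LinearProgram(out)
        try:
            lp.solve(out.objective_id or out.reaction_ids[0], "max")
            return out, flags
        except InfeasibleError:
            if not rid or out.reaction(rid).lb <= 0:
                continue
            out = out.copy()
            out.reaction(rid).lb = 0.0
            flags[f"{key}_lb_relaxed"] = True
    # final check
    lp = LinearProgram(out)
    try:
        lp.solve(out.objective_id or out.reaction_ids[0], "max")
    except InfeasibleError:
        flags["infeasible_after_relaxation"] = True
    return out, flags


def fva(
    model: MetabolicModel, reactions: list[str] | None = None
) -> tuple[pd.Series, pd.Series]:
    """Per-reaction attainable flux range under all current constraints."""
    lp = LinearProgram(model)
    reactions = reactions if reactions is not None else model.reaction_ids
    vmin = pd.Series(0.0, index=reactions)
    vmax = pd.Series(0.0, index=reactions)
    for rid in reactions:
        try:
            vmin[rid], _ = lp.solve(rid, "min", vector=False)
            vmax[rid], _ = lp.solve(rid, "max", vector=False)
        except InfeasibleError:
            raise
        except RuntimeError:
            vmin[rid] = vmax[rid] = 0.0
    # snap numerical dust to zero
    vmin[vmin.abs() < FLUX_ZERO_TOL] = 0.0
    vmax[vmax.abs() < FLUX_ZERO_TOL] = 0.0
    return vmin, vmax


def profile_from_model(
    maintained: MetabolicModel,
    sample_id: str,
    flags: dict | None = None,
    summary: str = "midpoint",
) -> FluxProfile:
    """FVA over all reactions of an already-maintained model."""
    vmin, vmax = fva(maintained)
    if summary == "midpoint":
        values = (vmin + vmax) / 2.0
    elif summary == "fba_vertex":
        _, vec = fba(maintained)
        values = vec.clip(lower=vmin, upper=vmax)
    else:
        raise ValueError(f"unknown flux summary {summary!r}")
    values[values.abs() < FLUX_ZERO_TOL] = 0.0
    return FluxProfile(
        sample_id=sample_id,
        values=values,
        fva_min=vmin,
        fva_max=vmax,
        feasibility_flags=dict(flags or {}),
    )


def flux_profile(
    model: MetabolicModel,
    expr: ExpressionProfile,
    kinetics: KineticTable,
    medium: MediumSpec,
    fraction: float = MAINTENANCE_FRACTION,
    summary: str = "midpoint",
    split: bool = True,
) -> FluxProfile:
    """Full per-sample pipeline: constrain → split → maintain → FVA.

    Deterministic given its inputs.  With ``split=True`` (default) the
    model is made irreversible first so every reported flux is
    nonnegative, which the log-ratio statistics downstream require.
    """
    sm = build_sample_model(model, expr, kinetics, medium)
    if split:
        sm = split_reversible(sm)
    maintained, flags = apply_maintenance(sm, fraction=fraction)
    return profile_from_model(maintained, expr.sample_id, flags, summary=summary)


def constrained_sample_model(
    model: MetabolicModel,
    expr: ExpressionProfile,
    kinetics: KineticTable,
    medium: MediumSpec,
    fraction: float = MAINTENANCE_FRACTION,
    split: bool = True,
) -> tuple[MetabolicModel, dict]:
    """The maintained per-sample model itself (used by knockout scans)."""
    sm = build_sample_model(model, expr, kinetics, medium)
    if split:
        sm = split_reversible(sm)
    return apply_maintenance(sm, fraction=fraction)


def write_flux_tsv(profiles: list[FluxProfile], path) -> None:
    """Reactions × samples matrix of flux midpoints."""
    df = pd.DataFrame({p.sample_id: p.values for p in profiles})
    df.index.name = "reaction_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
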