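"""Brute-force reaction-removal knockout oracle.

Independent of the package's solver layer: builds each LP as a dense
``scipy.optimize.linprog`` problem from scratch, *physically deletes*
the reactions a knockout disables (instead of zeroing their bounds),
and re-derives the FVA midpoints.  Shared by the unit tests and the
acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from senflux.network import MetabolicModel, evaluate_gpr

TAU = 1e-6


def _dense_lp(model: MetabolicModel, keep: list[str]):
    met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
    cols = [r for r in model.reactions if r.id in keep]
    A = np.zeros((len(met_index), len(cols)))
    for j, rxn in enumerate(cols):
        for met, coef in rxn.stoich.items():
            A[met_index[met], j] = coef
    bounds = [(r.lb, r.ub) for r in cols]
    return [r.id for r in cols], A, bounds


def _solve(A, bounds, j, sense):
    c = np.zeros(len(bounds))
    c[j] = 1.0 if sense == "min" else -1.0
    res = linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=bounds,
                  method="highs")
    if res.status == 2:
        return None
    if not res.success:
        raise RuntimeError(res.message)
    return res.fun if sense == "min" else -res.fun


def _feasible(A, bounds):
    res = linprog(np.zeros(len(bounds)), A_eq=A,
                  b_eq=np.zeros(A.shape[0]), bounds=bounds, method="highs")
    return res.status != 2


def _removed_midpoints(model: MetabolicModel, removed: set[str],
                       report: list[str]) -> pd.Series:
    keep = [r.id for r in model.reactions if r.id not in removed]
    ids, A, bounds = _dense_lp(model, keep)
    # relax maintenance bounds (biomass first, then ATP demand) if the
    # deletion is lethal under them
    for rid in (model.objective_id, model.atp_demand_id):
        if _feasible(A, bounds):
            break
        if rid and rid in ids:
            j = ids.index(rid)
            if bounds[j][0] > 0:
                bounds[j] = (0.0, bounds[j][1])
    vals = pd.Series(0.0, index=report)
    if not _feasible(A, bounds):
        return vals
    for rid in report:
        if rid in removed:
            continue
        j = ids.index(rid)
        lo = _solve(A, bounds, j, "min")
        hi = _solve(A, bounds, j, "max")
        if lo is None or hi is None:
            continue
        mid = (lo + hi) / 2.0
        vals[rid] = 0.0 if abs(mid) < TAU else mid
    return vals


def removal_oracle_matrix(model: MetabolicModel, baseline, expr,
                          kind: str) -> pd.DataFrame:
    """Ternary KO effect matrix by physical reaction removal."""
    report = [r.id for r in model.reactions if not r.is_transport]
    base = baseline.values.reindex(report).to_numpy()
    if kind == "gene":
        entities = sorted(model.genes)
        affected_of = {}
        for g in entities:
            values = dict(expr.values)
            values[g] = 0.0
            affected_of[g] = {
                r.id
                for r in model.reactions
                if r.gpr
                and evaluate_gpr(r.gpr, expr.values) > 0
                and evaluate_gpr(r.gpr, values) == 0
            }
    else:
        entities = sorted(model.metabolite_ids)
        affected_of = {
            m: {r.id for r in model.reactions if m in r.stoich}
            for m in entities
        }
    rows = []
    for ent in entities:
        removed = affected_of[ent]
        if not removed:
            rows.append(np.zeros(len(report), dtype=int))
            continue
        vals = _removed_midpoints(model, removed, report).to_numpy()
        delta = vals - base
        rows.append(np.where(delta > TAU, 1, np.where(delta < -TAU, -1, 0)))
    return pd.DataFrame(np.array(rows, dtype=int), index=entities,
                        columns=report)
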