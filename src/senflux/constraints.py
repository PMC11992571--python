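"""Per-sample constrained model construction.

The capacity of an enzyme-catalysed reaction is bounded above by a
Michaelis–Menten-style Vmax: ``Vmax_j = kcat_j · E_j · σ``, where ``E_j``
is the enzyme abundance estimated from gene expression through the GPR
rule (AND = min over complex subunits, OR = sum over isozymes) and σ is
a single global abundance→flux conversion constant (default 1; a global
constant preserves every rank and ratio the downstream statistics use).
Nutrient availability enters through exchange uptake bounds: exchanges
listed in the medium get their stated maximum uptake, every other
exchange gets uptake zero, secretion is unrestricted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .network import UNCONSTRAINED, MetabolicModel, evaluate_gpr, parse_gpr


class ConstraintError(ValueError):
    pass


@dataclass
class KineticTable:
    """reaction id → kcat (events per unit time), plus the global σ."""

    kcat: dict[str, float]
    sigma: float = 1.0

    def __post_init__(self):
        bad = {r: k for r, k in self.kcat.items() if not k > 0}
        if bad:
            raise ConstraintError(f"kcat must be > 0; offending entries: {bad}")

    @classmethod
    def read_tsv(cls, path, sigma: float = 1.0) -> "KineticTable":
        df = pd.read_csv(path, sep="\t")
        return cls(kcat=dict(zip(df["reaction_id"], df["kcat"].astype(float))),
                   sigma=sigma)

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"reaction_id": sorted(self.kcat), "kcat": [self.kcat[r] for r in sorted(self.kcat)]}
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class MediumSpec:
    """exchange reaction id → maximum uptake rate (nonnegative, flux units)."""

    uptake: dict[str, float]

    def __post_init__(self):
        bad = {r: u for r, u in self.uptake.items() if u < 0}
        if bad:
            raise ConstraintError(f"uptake rates must be >= 0: {bad}")

    @classmethod
    def read_tsv(cls, path) -> "MediumSpec":
        df = pd.read_csv(path, sep="\t")
        return cls(uptake=dict(zip(df["exchange_id"], df["max_uptake"].astype(float))))

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"exchange_id": sorted(self.uptake),
             "max_uptake": [self.uptake[r] for r in sorted(self.uptake)]}
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class ExpressionProfile:
    """One sample's FPKM-like expression values with study metadata."""

    sample_id: str
    values: dict[str, float]
    study_id: str = ""
    group: str | None = None  # "proliferative" | "senescent"
    passage: int | None = None

    def __post_init__(self):
        if self.group is not None and self.group not in (
            "proliferative",
            "senescent",
        ):
            raise ConstraintError(
                f"sample {self.sample_id}: group must be proliferative/senescent"
            )
        bad = {g: v for g, v in self.values.items() if v < 0}
        if bad:
            raise ConstraintError(
                f"sample {self.sample_id}: negative expression for {sorted(bad)[:3]}"
            )


def read_expression_tsv(matrix_path, metadata_path) -> list[ExpressionProfile]:
    """Read genes × samples expression TSV plus the sample metadata TSV.

    Metadata columns: ``sample_id``, ``study_id``, and ``group`` or
    ``passage`` (one of the two per study design).
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    profiles = []
    for _, row in meta.iterrows():
        sid = row["sample_id"]
        if sid not in mat.columns:
            raise ConstraintError(f"sample {sid} in metadata but not in matrix")
        group = row.get("group")
        passage = row.get("passage")
        profiles.append(
            ExpressionProfile(
                sample_id=sid,
                values=mat[sid].to_dict(),
                study_id=str(row.get("study_id", "")),
                group=None if pd.isna(group) else str(group),
                passage=None if pd.isna(passage) else int(passage),
            )
        )
    return profiles


def write_expression_tsv(profiles: list[ExpressionProfile], matrix_path,
                         metadata_path) -> None:
    genes = sorted(profiles[0].values)
    mat = pd.DataFrame(
        {p.sample_id: [p.values[g] for g in genes] for p in profiles}, index=genes
    )
    mat.index.name = "gene"
    mat.to_csv(matrix_path, sep="\t", float_format="%.10g")
    meta = pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in profiles],
            "study_id": [p.study_id for p in profiles],
            "group": [p.group if p.group is not None else "" for p in profiles],
            "passage": [p.passage if p.passage is not None else "" for p in profiles],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Capacity bounds
# ---------------------------------------------------------------------------


def enzyme_abundance(model: MetabolicModel, expr: ExpressionProfile) -> dict[str, float]:
    """Per-reaction enzyme abundance from the GPR rule.

    Reactions with an empty GPR map to :data:`UNCONSTRAINED`.
    """
    out = {}
    for rxn in model.reactions:
        ast = parse_gpr(rxn.gpr)
        out[rxn.id] = UNCONSTRAINED if ast is None else evaluate_gpr(ast, expr.values)
    return out


def vmax_bounds(abundance: dict[str, float], kinetics: KineticTable) -> dict[str, float]:
    """Vmax_j = kcat_j × abundance_j × σ for reactions listed in the table.

    Reactions absent from the table, or with unconstrained abundance,
    are omitted (they keep their default upper bound).
    """
    out = {}
    for rid, ab in abundance.items():
        if rid not in kinetics.kcat or ab == UNCONSTRAINED:
            continue
        out[rid] = kinetics.kcat[rid] * ab * kinetics.sigma
    return out


def build_sample_model(
    model: MetabolicModel,
    expr: ExpressionProfile,
    kinetics: KineticTable,
    medium: MediumSpec,
) -> MetabolicModel:
    """Constrained copy of *model* for one expression sample.

    Applies (i) Vmax upper bounds to GPR-bearing reactions with kinetic
    parameters, (ii) medium uptake bounds to listed exchanges, and
    (iii) zero uptake for every other exchange (secretion stays open).
    The input model is never mutated.
    """
    exchange_ids = {r.id for r in model.reactions if r.is_exchange}
    bad = set(medium.uptake) - exchange_ids
    if bad:
        raise ConstraintError(
            f"medium references non-exchange reactions: {sorted(bad)}"
        )
    out = model.copy()
    vmax = vmax_bounds(enzyme_abundance(model, expr), kinetics)
    for rxn in out.reactions:
        if rxn.id in vmax:
            rxn.ub = min(rxn.ub, vmax[rxn.id])
            rxn.lb = min(rxn.lb, rxn.ub)  # keep lb <= ub; uptake untouched otherwise
            if rxn.reversible:
                rxn.lb = max(rxn.lb, -vmax[rxn.id])
        if rxn.is_exchange:
            # uptake is the negative flux direction of "met -> Ø"
            rxn.lb = -medium.uptake.get(rxn.id, 0.0)
    return out
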