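"""Stoichiometric network data model and I/O.

A :class:`MetabolicModel` is the central container: metabolites with
bracketed compartment suffixes (``"mev1[c]"``), reactions with signed
stoichiometry, flux bounds, a subsystem (pathway) label, and a
gene-protein-reaction (GPR) boolean rule mapping gene abundances to an
enzyme-capacity estimate.  The native serialisation is a small JSON
schema (documented in :func:`write_model`); SBML is deliberately not the
native format — the models this package works with are processed
matrices, and a minimal schema keeps fixtures readable and diffable.

GPR semantics follow the standard enzyme-complex/isozyme convention:
``AND`` nodes (subunits of one complex) take the *minimum* of their
children, ``OR`` nodes (isozymes) take the *sum*.  Genes missing from an
abundance map contribute 0 (the reaction may become blocked); this is
logged, not fatal.
"""

from __future__ import annotations

import copy
import json
import logging
import math
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: Capacity value meaning "no expression constraint" (empty GPR).
UNCONSTRAINED = math.inf

_COMPARTMENT_RE = re.compile(r"\[(\w+)\]$")


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class GPRSyntaxError(ValueError):
    """Raised when a GPR rule cannot be parsed."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(rule: str) -> list[str]:
    return _TOKEN_RE.findall(rule)


class _GPRParser:
    """Recursive-descent parser for ``gene``, ``and``, ``or``, parentheses.

    Grammar (lowest precedence first)::

        expr   := term ("or" term)*
        term   := factor ("and" factor)*
        factor := gene | "(" expr ")"
    """

    def __init__(self, rule: str):
        self.tokens = _tokenize(rule)
        self.pos = 0
        self.rule = rule

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of GPR rule: {self.rule!r}")
        self.pos += 1
        return tok

    def parse(self) -> tuple:
        node = self.expr()
        if self.peek() is not None:
            raise GPRSyntaxError(
                f"trailing tokens at {self.peek()!r} in GPR rule {self.rule!r}"
            )
        return node

    def expr(self) -> tuple:
        children = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            children.append(self.term())
        return children[0] if len(children) == 1 else ("or", children)

    def term(self) -> tuple:
        children = [self.factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            children.append(self.factor())
        return children[0] if len(children) == 1 else ("and", children)

    def factor(self) -> tuple:
        tok = self.take()
        if tok == "(":
            node = self.expr()
            if self.take() != ")":
                raise GPRSyntaxError(f"unbalanced parentheses in {self.rule!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r} in {self.rule!r}")
        return ("gene", tok)


def parse_gpr(rule: str) -> tuple | None:
    """Parse a GPR rule string into an AST; ``None`` for an empty rule."""
    if rule is None or not rule.strip():
        return None
    return _GPRParser(rule).parse()


def gpr_genes(rule: str) -> set[str]:
    """The set of gene identifiers referenced by a GPR rule."""
    ast = parse_gpr(rule)
    out: set[str] = set()

    def walk(node):
        if node is None:
            return
        if node[0] == "gene":
            out.add(node[1])
        else:
            for child in node[1]:
                walk(child)

    walk(ast)
    return out


def evaluate_gpr(rule: str | tuple | None, abundance: dict[str, float]) -> float:
    """Evaluate a GPR rule against gene abundances.

    AND returns the minimum of its children (complex limited by its
    scarcest subunit); OR returns the sum (isozymes act in parallel).
    An empty rule returns :data:`UNCONSTRAINED`.  Genes absent from
    *abundance* contribute 0 and a warning is logged.
    """
    ast = parse_gpr(rule) if isinstance(rule, str) or rule is None else rule
    if ast is None:
        return UNCONSTRAINED

    def walk(node) -> float:
        kind = node[0]
        if kind == "gene":
            gene = node[1]
            if gene not in abundance:
                logger.warning("gene %s absent from abundance map; treated as 0", gene)
                return 0.0
            return float(abundance[gene])
        values = [walk(child) for child in node[1]]
        return min(values) if kind == "and" else sum(values)

    return walk(ast)


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""

    def __post_init__(self):
        if not self.compartment:
            m = _COMPARTMENT_RE.search(self.id)
            if m:
                self.compartment = m.group(1)


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lb: float = 0.0
    ub: float = 1000.0
    gpr: str = ""
    subsystem: str = ""
    is_exchange: bool = False
    is_transport: bool = False
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.lb < 0.0


@dataclass
class MetabolicModel:
    """A stoichiometric network with bounds, GPR rules and subsystems."""

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    objective_id: str = ""
    atp_demand_id: str = ""
    name: str = ""

    # -- lookups ----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def subsystems(self) -> dict[str, str]:
        """reaction id → subsystem label."""
        return {r.id: r.subsystem for r in self.reactions}

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        met_ids = self.metabolite_ids
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = self.reaction_ids
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        met_set = set(met_ids)
        gene_set = set(self.genes)
        for met in self.metabolites:
            m = _COMPARTMENT_RE.search(met.id)
            if m and met.compartment and m.group(1) != met.compartment:
                raise ModelValidationError(
                    f"metabolite {met.id}: compartment field {met.compartment!r} "
                    f"does not match id suffix [{m.group(1)}]"
                )
        for rxn in self.reactions:
            if not rxn.stoich:
                raise ModelValidationError(f"reaction {rxn.id}: empty stoichiometry")
            for met, coef in rxn.stoich.items():
                if met not in met_set:
                    raise ModelValidationError(
                        f"reaction {rxn.id}: undeclared metabolite {met}"
                    )
                if coef == 0:
                    raise ModelValidationError(
                        f"reaction {rxn.id}: zero coefficient for {met}"
                    )
            if rxn.lb > rxn.ub:
                raise ModelValidationError(
                    f"reaction {rxn.id}: lb {rxn.lb} > ub {rxn.ub}"
                )
            if rxn.is_exchange and len(rxn.stoich) != 1:
                raise ModelValidationError(
                    f"exchange reaction {rxn.id} must touch exactly one metabolite"
                )
            try:
                missing = gpr_genes(rxn.gpr) - gene_set
            except GPRSyntaxError as exc:
                raise ModelValidationError(f"reaction {rxn.id}: {exc}") from exc
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id}: GPR references undeclared genes "
                    f"{sorted(missing)}"
                )
        if self.objective_id and self.objective_id not in set(rxn_ids):
            raise ModelValidationError(
                f"objective_id {self.objective_id!r} not a reaction"
            )
        if self.atp_demand_id and self.atp_demand_id not in set(rxn_ids):
            raise ModelValidationError(
                f"atp_demand_id {self.atp_demand_id!r} not a reaction"
            )

    # -- matrix views -----------------------------------------------------
    def stoichiometric_matrix(self):
        """Dense S as a pandas DataFrame (metabolites × reactions)."""
        import pandas as pd

        S = pd.DataFrame(
            0.0, index=self.metabolite_ids, columns=self.reaction_ids
        )
        for rxn in self.reactions:
            for met, coef in rxn.stoich.items():
                S.loc[met, rxn.id] = coef
        return S

    def dead_end_metabolites(self) -> list[str]:
        """Internal metabolites lacking a producer or a consumer.

        A reversible reaction counts as both.  Metabolites touched by an
        exchange reaction are boundary species and never flagged.
        """
        produced: set[str] = set()
        consumed: set[str] = set()
        boundary: set[str] = set()
        for rxn in self.reactions:
            for met, coef in rxn.stoich.items():
                if rxn.is_exchange:
                    boundary.add(met)
                if coef > 0 or rxn.reversible:
                    produced.add(met)
                if coef < 0 or rxn.reversible:
                    consumed.add(met)
        return [
            m.id
            for m in self.metabolites
            if m.id not in boundary
            and (m.id not in produced or m.id not in consumed)
        ]


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "name": model.name,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoich": {k: r.stoich[k] for k in sorted(r.stoich)},
                "lb": r.lb,
                "ub": r.ub,
                "gpr": r.gpr,
                "subsystem": r.subsystem,
                "exchange": r.is_exchange,
                "transport": r.is_transport,
            }
            for r in model.reactions
        ],
        "genes": list(model.genes),
        "objective_id": model.objective_id,
        "atp_demand_id": model.atp_demand_id,
    }


def model_from_dict(data: dict) -> MetabolicModel:
    try:
        model = MetabolicModel(
            metabolites=[
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    compartment=m.get("compartment", ""),
                )
                for m in data["metabolites"]
            ],
            reactions=[
                Reaction(
                    id=r["id"],
                    stoich={k: float(v) for k, v in r["stoich"].items()},
                    lb=float(r.get("lb", 0.0)),
                    ub=float(r.get("ub", 1000.0)),
                    gpr=r.get("gpr", ""),
                    subsystem=r.get("subsystem", ""),
                    is_exchange=bool(r.get("exchange", False)),
                    is_transport=bool(r.get("transport", False)),
                    name=r.get("name", ""),
                )
                for r in data["reactions"]
            ],
            genes=list(data.get("genes", [])),
            objective_id=data.get("objective_id", ""),
            atp_demand_id=data.get("atp_demand_id", ""),
            name=data.get("name", ""),
        )
    except KeyError as exc:
        raise ModelValidationError(f"model JSON missing required key: {exc}") from exc
    model.validate()
    return model


def load_model(path) -> MetabolicModel:
    """Load and validate a model from the JSON schema."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"{path}: not valid JSON ({exc})") from exc
    return model_from_dict(data)


def write_model(model: MetabolicModel, path) -> None:
    """Write a model as canonical JSON (sorted keys, fixed indent).

    Schema: top-level keys ``metabolites[]``, ``reactions[]`` (each with
    ``stoich`` map, ``lb``, ``ub``, ``gpr``, ``subsystem``, ``exchange``,
    ``transport``), ``genes[]``, ``objective_id``, ``atp_demand_id``.
    Exchange reactions are written as ``met → ∅`` with coefficient −1;
    uptake is the negative flux direction, so the medium uptake limit u
    appears as ``lb = −u``.
    """
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_stoichiometry_tsv(model: MetabolicModel, path) -> None:
    """Debugging export of S (metabolites × reactions) as TSV."""
    model.stoichiometric_matrix().to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Reversibility handling
# ---------------------------------------------------------------------------


def split_reversible(model: MetabolicModel) -> MetabolicModel:
    """Replace each reversible reaction by an irreversible forward/backward pair.

    ``R`` with bounds (lb < 0, ub) becomes ``R_f`` with bounds (0, ub) and
    ``R_b`` with negated stoichiometry and bounds (0, −lb); the net flux of
    the original reaction is ``v(R_f) − v(R_b)``, so every LP over the
    original model has the same optimal objective value over the split
    model.  Irreversible reactions are untouched.  All downstream
    statistics run on split models so fluxes are nonnegative.
    """
    out = MetabolicModel(
        metabolites=copy.deepcopy(model.metabolites),
        genes=list(model.genes),
        objective_id=model.objective_id,
        atp_demand_id=model.atp_demand_id,
        name=model.name,
    )
    for rxn in model.reactions:
        if not rxn.reversible:
            out.reactions.append(copy.deepcopy(rxn))
            continue
        fwd = copy.deepcopy(rxn)
        fwd.id = rxn.id + "_f"
        fwd.lb, fwd.ub = 0.0, max(rxn.ub, 0.0)
        bwd = copy.deepcopy(rxn)
        bwd.id = rxn.id + "_b"
        bwd.stoich = {k: -v for k, v in rxn.stoich.items()}
        bwd.lb, bwd.ub = 0.0, -rxn.lb
        out.reactions.append(fwd)
        out.reactions.append(bwd)
        if model.objective_id == rxn.id:
            out.objective_id = fwd.id
        if model.atp_demand_id == rxn.id:
            out.atp_demand_id = fwd.id
    return out
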