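"""Synthetic toy network and expression data with planted senescence structure.

The generator exists so the whole pipeline can be exercised, end to end,
on data whose truth is known.  The toy network mimics — at cartoon
scale — the topology the analysis is designed to detect: a glycolysis-like
trunk feeding ATP and pyruvate, a six-step linear "mevalonate" chain
(one gene per step) whose product feeds an eight-reaction "lipid"
branch that is essential for biomass, a small isoprenoid secretion
branch off the chain end, independent decoy pathways, and a biomass
pseudo-reaction consuming pyruvate, nucleotide precursor, lipid and ATP.
Two redundant carbon sources (glucose and fructose) enter through their
own transporters, as in any realistic culture medium, so no single
hexose route is essential.

Planted structure: in senescent samples (or linearly along passage in
time-series mode) the six chain genes are down-regulated by
``effect_lfc`` log2 units (with small per-study jitter, sd 0.1, modelling
between-study heterogeneity).  Because the chain is the enzyme-limited
step for lipid synthesis, the planted knockdown propagates to lower
chain, lipid and biomass fluxes — the ground truth the recovery tests
assert.

Expression noise is multiplicative lognormal (positive support, matching
FPKM behaviour); kcat is 1 for every enzymatic reaction so expression
alone drives capacity differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constraints import ExpressionProfile, KineticTable, MediumSpec
from .network import MetabolicModel, Metabolite, Reaction

#: baseline mean expression ranges (log-uniform) per gene role
BASELINE_RANGES = {
    "trunk": (10.0, 20.0),
    "mevalonate": (2.0, 3.0),
    "lipid": (5.0, 10.0),
    "isoprenoid": (0.5, 1.0),
    "decoy": (3.0, 6.0),
}

#: passage points of the default time-series design (a 9-point fibroblast
#: passaging course with duplicate cultures at each point)
DEFAULT_PASSAGES = (13, 16, 19, 22, 25, 28, 31, 34, 37)


@dataclass
class SyntheticSpec:
    """Study-design knobs for the synthetic benchmark.

    Defaults are the conditions the recovery tests run under: five
    case–control studies of 5 vs 5 samples, a planted −1 log2 effect on
    the chain genes, lognormal expression noise sd 0.3; time-series mode
    uses 9 passages with 2 replicates each and a total planted decline
    of log2(3) ≈ 1.585 (a ≈3-fold drop across the course).
    """

    n_studies: int = 5
    samples_per_group: int = 5
    passages: tuple = DEFAULT_PASSAGES
    replicates_per_passage: int = 2
    effect_lfc: float = -1.0
    ts_total_lfc: float = -float(np.log2(3.0))
    study_jitter_sd: float = 0.1
    noise_sd: float = 0.3
    seed: int = 0
    n_decoy_pathways: int = 3
    decoy_chain_len: int = 6
    mev_chain_len: int = 6
    lipid_chain_len: int = 8

    def __post_init__(self):
        if self.n_studies < 2 or self.samples_per_group < 2:
            raise ValueError("need >= 2 studies and >= 2 samples per group")
        if len(self.passages) < 3:
            raise ValueError("need >= 3 passages for time-series mode")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class GroundTruth:
    """What was planted, for the recovery tests."""

    planted_down_genes: set = field(default_factory=set)
    planted_down_subsystems: set = field(default_factory=set)
    planted_agonist_metabolites: set = field(default_factory=set)
    neutral_genes: set = field(default_factory=set)
    neutral_subsystems: set = field(default_factory=set)
    gene_roles: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "planted_down_genes": sorted(self.planted_down_genes),
            "planted_down_subsystems": sorted(self.planted_down_subsystems),
            "planted_agonist_metabolites": sorted(self.planted_agonist_metabolites),
            "neutral_genes": sorted(self.neutral_genes),
            "neutral_subsystems": sorted(self.neutral_subsystems),
            "gene_roles": dict(sorted(self.gene_roles.items())),
        }


# ---------------------------------------------------------------------------
# Toy network
# ---------------------------------------------------------------------------


def make_toy_network(spec: SyntheticSpec | None = None, seed: int = 0):
    """Deterministic toy network with planted senescence targets.

    Returns ``(model, truth)``.  The network layout is fixed given the
    size knobs in *spec*; *seed* is accepted for interface symmetry but
    the construction is deterministic.
    """
    spec = spec or SyntheticSpec()
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    roles: dict[str, str] = {}

    def met(mid):
        mets.append(Metabolite(id=mid))
        return mid

    def rxn(rid, stoich, gene="", subsystem="", exchange=False, transport=False,
            lb=0.0, ub=1000.0):
        rxns.append(
            Reaction(id=rid, stoich=stoich, gpr=gene, subsystem=subsystem,
                     is_exchange=exchange, is_transport=transport, lb=lb, ub=ub)
        )

    # trunk: two redundant hexose routes -> pyruvate + ATP
    for sugar in ("glc", "fru"):
        met(f"{sugar}[e]")
        met(f"{sugar}[c]")
        rxn(f"EX_{sugar}", {f"{sugar}[e]": -1.0}, subsystem="exchange",
            exchange=True)
        rxn(f"T_{sugar}", {f"{sugar}[e]": -1.0, f"{sugar}[c]": 1.0},
            subsystem="transport", transport=True, lb=-1000.0)
    met("pyr[c]")
    met("atp[c]")
    met("accoa[c]")
    met("nuc[c]")
    rxn("GLY_glc", {"glc[c]": -1.0, "pyr[c]": 2.0, "atp[c]": 2.0},
        gene="g_glyA", subsystem="glycolysis")
    rxn("GLY_fru", {"fru[c]": -1.0, "pyr[c]": 2.0, "atp[c]": 2.0},
        gene="g_glyB", subsystem="glycolysis")
    rxn("PDH", {"pyr[c]": -1.0, "accoa[c]": 1.0}, gene="g_pdh",
        subsystem="glycolysis")
    rxn("NUCSYN", {"pyr[c]": -1.0, "atp[c]": -2.0, "nuc[c]": 1.0},
        gene="g_nuc", subsystem="nucleotide")
    rxn("OXPHOS", {"accoa[c]": -1.0, "atp[c]": 10.0}, gene="g_oxp",
        subsystem="energy")
    rxn("ATPM", {"atp[c]": -1.0}, subsystem="energy", ub=10.0)
    # overflow metabolism: lactate-like secretion keeps pyruvate disposable
    met("lac[c]")
    met("lac[e]")
    rxn("LDH", {"pyr[c]": -1.0, "lac[c]": 1.0}, gene="g_ldh",
        subsystem="fermentation")
    rxn("T_lac", {"lac[c]": -1.0, "lac[e]": 1.0}, subsystem="transport",
        transport=True)
    rxn("EX_lac", {"lac[e]": -1.0}, subsystem="exchange", exchange=True)
    roles.update(g_glyA="trunk", g_glyB="trunk", g_pdh="trunk", g_nuc="trunk",
                 g_oxp="trunk", g_ldh="trunk")

    # mevalonate-like chain: one gene per step, enzyme-limited by design
    prev = "accoa[c]"
    for k in range(1, spec.mev_chain_len + 1):
        mid = met(f"mev{k}[c]")
        stoich = {prev: -2.0 if k == 1 else -1.0, mid: 1.0}
        if k == 2:
            stoich["atp[c]"] = -1.0
        rxn(f"MEV{k}", stoich, gene=f"g_mev{k}", subsystem="mevalonate")
        roles[f"g_mev{k}"] = "mevalonate"
        prev = mid
    chain_end = prev

    # lipid branch: biomass-essential consumer of the chain product
    for k in range(1, spec.lipid_chain_len + 1):
        mid = met(f"lp{k}[c]" if k < spec.lipid_chain_len else "lipid[c]")
        rxn(f"LIP{k}", {prev: -1.0, mid: 1.0}, gene=f"g_lip{k}",
            subsystem="lipid")
        roles[f"g_lip{k}"] = "lipid"
        prev = mid

    # small isoprenoid secretion branch off the chain end
    met("iso[c]")
    met("iso[e]")
    rxn("ISO1", {chain_end: -1.0, "iso[c]": 1.0}, gene="g_iso",
        subsystem="isoprenoid")
    rxn("T_iso", {"iso[c]": -1.0, "iso[e]": 1.0}, subsystem="transport",
        transport=True)
    rxn("EX_iso", {"iso[e]": -1.0}, subsystem="exchange", exchange=True)
    roles["g_iso"] = "isoprenoid"

    # decoy pathways: independent genes, no planted effect
    for d in range(1, spec.n_decoy_pathways + 1):
        prev_m = "pyr[c]"
        for k in range(1, spec.decoy_chain_len + 1):
            mid = met(f"d{d}m{k}[c]")
            rxn(f"DEC{d}_{k}", {prev_m: -1.0, mid: 1.0}, gene=f"g_dec{d}_{k}",
                subsystem=f"decoy{d}")
            roles[f"g_dec{d}_{k}"] = "decoy"
            prev_m = mid
        met(f"d{d}out[e]")
        rxn(f"T_dec{d}", {prev_m: -1.0, f"d{d}out[e]": 1.0},
            subsystem="transport", transport=True)
        rxn(f"EX_dec{d}", {f"d{d}out[e]": -1.0}, subsystem="exchange",
            exchange=True)

    rxn("BIOMASS",
        {"pyr[c]": -1.0, "nuc[c]": -1.0, "lipid[c]": -1.0, "atp[c]": -5.0},
        subsystem="biomass")

    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=sorted(roles),
        objective_id="BIOMASS",
        atp_demand_id="ATPM",
        name="toy_senescence_network",
    )
    model.validate()
    truth = GroundTruth(
        planted_down_genes={f"g_mev{k}" for k in range(1, spec.mev_chain_len + 1)},
        planted_down_subsystems={"mevalonate", "lipid"},
        planted_agonist_metabolites={
            f"mev{k}[c]" for k in range(1, spec.mev_chain_len + 1)
        },
        neutral_genes={g for g, r in roles.items() if r == "decoy"},
        neutral_subsystems={f"decoy{d}" for d in range(1, spec.n_decoy_pathways + 1)},
        gene_roles=roles,
    )
    return model, truth


def toy_kinetics(model: MetabolicModel) -> KineticTable:
    """All-ones kcat for every GPR-bearing reaction (σ = 1)."""
    return KineticTable(kcat={r.id: 1.0 for r in model.reactions if r.gpr})


def toy_medium() -> MediumSpec:
    """Both hexoses available at uptake 10."""
    return MediumSpec(uptake={"EX_glc": 10.0, "EX_fru": 10.0})


def chain_network(capacity: float = 14.0, uptake: float = 10.0) -> MetabolicModel:
    """Minimal 3-reaction chain EX_A → R1 → EX_B used in worked examples.

    FBA maximising EX_B gives ``min(uptake, capacity)``; with a biomass
    lower bound b the FVA range of R1 is ``[b, min(uptake, capacity)]``.
    """
    model = MetabolicModel(
        metabolites=[Metabolite(id="A[c]"), Metabolite(id="B[c]")],
        reactions=[
            Reaction(id="EX_A", stoich={"A[c]": -1.0}, lb=-uptake, ub=1000.0,
                     is_exchange=True, subsystem="exchange"),
            Reaction(id="R1", stoich={"A[c]": -1.0, "B[c]": 1.0}, ub=capacity,
                     gpr="g1", subsystem="chain"),
            Reaction(id="EX_B", stoich={"B[c]": -1.0}, ub=1000.0,
                     is_exchange=True, subsystem="exchange"),
        ],
        genes=["g1"],
        objective_id="EX_B",
        name="chain3",
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def _baseline_means(model: MetabolicModel, truth: GroundTruth,
                    rng: np.random.Generator) -> dict[str, float]:
    means = {}
    for gene in model.genes:
        lo, hi = BASELINE_RANGES[truth.gene_roles[gene]]
        means[gene] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return means


def simulate_expression(
    model: MetabolicModel,
    truth: GroundTruth,
    spec: SyntheticSpec,
    mode: str = "case_control",
    seed: int | None = None,
) -> list[ExpressionProfile]:
    """Simulate multi-study expression profiles over the toy network.

    ``case_control``: for each study, ``samples_per_group`` proliferative
    and senescent samples; senescent samples down-shift the planted
    genes by ``effect_lfc`` log2 units plus a per-study jitter.
    ``timeseries``: one study; ``replicates_per_passage`` samples per
    passage; the planted shift grows linearly from 0 at the first
    passage to ``ts_total_lfc`` at the last.

    Values are ``mean · 2^shift · exp(N(0, noise_sd))``; bit-identical
    for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    means = _baseline_means(model, truth, rng)
    planted = truth.planted_down_genes
    genes = list(model.genes)
    profiles: list[ExpressionProfile] = []

    def draw(shifts: dict[str, float]) -> dict[str, float]:
        noise = rng.normal(0.0, spec.noise_sd, size=len(genes))
        return {
            g: means[g] * 2.0 ** shifts.get(g, 0.0) * float(np.exp(noise[i]))
            for i, g in enumerate(genes)
        }

    if mode == "case_control":
        for s in range(1, spec.n_studies + 1):
            study = f"study{s}"
            jitter = float(rng.normal(0.0, spec.study_jitter_sd))
            for grp, tag in (("proliferative", "pro"), ("senescent", "sen")):
                shifts = (
                    {g: spec.effect_lfc + jitter for g in planted}
                    if grp == "senescent"
                    else {}
                )
                for i in range(1, spec.samples_per_group + 1):
                    profiles.append(
                        ExpressionProfile(
                            sample_id=f"{study}_{tag}{i}",
                            study_id=study,
                            group=grp,
                            values=draw(shifts),
                        )
                    )
    elif mode == "timeseries":
        p = np.asarray(spec.passages, dtype=float)
        frac = (p - p.min()) / (p.max() - p.min())
        for j, passage in enumerate(spec.passages):
            shifts = {g: spec.ts_total_lfc * float(frac[j]) for g in planted}
            for rep in range(1, spec.replicates_per_passage + 1):
                profiles.append(
                    ExpressionProfile(
                        sample_id=f"hdf_p{passage}_r{rep}",
                        study_id="hdf_timeseries",
                        passage=int(passage),
                        values=draw(shifts),
                    )
                )
    else:
        raise ValueError(f"unknown simulation mode {mode!r}")
    return profiles


# ---------------------------------------------------------------------------
# Random small networks (oracle / property testing)
# ---------------------------------------------------------------------------

_GPR_PATTERNS = (
    "",
    "{0}",
    "{0} or {1}",
    "{0} and {1}",
    "({0} and {1}) or {2}",
)


def random_network(rng: np.random.Generator, max_reactions: int = 20) -> MetabolicModel:
    """Random small feasible network for oracle-equivalence testing.

    A linear backbone M0 → … → Mk with an uptake exchange at the head
    and a secreting exchange (the objective) at the tail, plus random
    cross reactions and random GPR rules.  All bounds are finite so
    every LP is bounded; v = 0 is always feasible before maintenance.
    """
    n_chain = int(rng.integers(3, 7))
    n_extra = int(rng.integers(0, max(1, max_reactions - n_chain - 2 - 1)))
    n_genes = int(rng.integers(3, 8))
    genes = [f"g{i}" for i in range(n_genes)]
    mets = [Metabolite(id=f"M{i}[c]") for i in range(n_chain + 1)]
    rxns = [
        Reaction(id="EX_in", stoich={"M0[c]": -1.0},
                 lb=-float(rng.integers(5, 15)), ub=50.0, is_exchange=True)
    ]

    def random_gpr():
        pat = _GPR_PATTERNS[int(rng.integers(0, len(_GPR_PATTERNS)))]
        picks = rng.choice(len(genes), size=3, replace=False)
        return pat.format(*[genes[i] for i in picks])

    for i in range(n_chain):
        rxns.append(
            Reaction(
                id=f"R{i}",
                stoich={f"M{i}[c]": -1.0, f"M{i + 1}[c]": 1.0},
                lb=-float(rng.integers(0, 6)) if rng.random() < 0.3 else 0.0,
                ub=float(rng.integers(2, 20)),
                gpr=random_gpr(),
            )
        )
    for j in range(n_extra):
        a, b = rng.choice(n_chain + 1, size=2, replace=False)
        rxns.append(
            Reaction(
                id=f"X{j}",
                stoich={f"M{a}[c]": -float(rng.integers(1, 3)),
                        f"M{b}[c]": float(rng.integers(1, 3))},
                ub=float(rng.integers(2, 20)),
                gpr=random_gpr(),
            )
        )
    rxns.append(
        Reaction(id="EX_out", stoich={f"M{n_chain}[c]": -1.0}, ub=50.0,
                 is_exchange=True)
    )
    model = MetabolicModel(
        metabolites=mets, reactions=rxns, genes=genes, objective_id="EX_out",
        name="random_net",
    )
    model.validate()
    return model


def random_abundance(model: MetabolicModel, rng: np.random.Generator) -> dict[str, float]:
    return {g: float(rng.uniform(0.5, 10.0)) for g in model.genes}
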