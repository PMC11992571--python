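"""Network data model, GPR semantics, JSON round-trips, reversibility."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senflux.network import (
    GPRSyntaxError,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    UNCONSTRAINED,
    evaluate_gpr,
    gpr_genes,
    load_model,
    model_from_dict,
    model_to_dict,
    split_reversible,
    write_model,
)
from senflux.solver import fba
from senflux.synthdata import random_abundance, random_network


class TestGPR:
    @pytest.mark.parametrize(
        "rule,abundance,expected",
        [
            ("(g1 and g2) or g3", {"g1": 4, "g2": 2, "g3": 5}, 7.0),
            ("g1", {"g1": 3.5}, 3.5),
            ("g1 or g2", {"g1": 1, "g2": 2}, 3.0),
            ("g1 and g2", {"g1": 1, "g2": 2}, 1.0),
            ("(g1 or g2) and g3", {"g1": 1, "g2": 2, "g3": 2.5}, 2.5),
            ("G1 AND G2", {"G1": 4, "G2": 6}, 4.0),  # keyword case-insensitive
        ],
    )
    def test_and_min_or_sum(self, rule, abundance, expected):
        assert evaluate_gpr(rule, abundance) == pytest.approx(expected)

    def test_empty_rule_is_unconstrained(self):
        assert evaluate_gpr("", {}) == UNCONSTRAINED
        assert evaluate_gpr(None, {}) == UNCONSTRAINED
        assert math.isinf(UNCONSTRAINED)

    def test_missing_gene_contributes_zero_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="senflux.network"):
            assert evaluate_gpr("(g1 and g2)", {"g1": 4}) == 0.0
        assert any("g2" in r.message for r in caplog.records)

    @pytest.mark.parametrize("bad", ["g1 and", "(g1 or g2", "and g1", "g1 ) g2"])
    def test_syntax_errors(self, bad):
        with pytest.raises(GPRSyntaxError):
            evaluate_gpr(bad, {"g1": 1, "g2": 1})

    def test_gene_extraction(self):
        assert gpr_genes("(gA and gB) or gC") == {"gA", "gB", "gC"}

    @given(
        base=st.dictionaries(
            st.sampled_from(["g1", "g2", "g3"]),
            st.floats(0, 100, allow_nan=False),
            min_size=3,
        ),
        bump=st.floats(0, 50, allow_nan=False),
        gene=st.sampled_from(["g1", "g2", "g3"]),
        rule=st.sampled_from(
            ["g1 and g2", "g1 or g2", "(g1 and g2) or g3", "(g1 or g3) and g2"]
        ),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_abundance(self, base, bump, gene, rule):
        """Raising any gene's abundance never lowers the enzyme estimate."""
        before = evaluate_gpr(rule, base)
        raised = dict(base)
        raised[gene] = raised[gene] + bump
        assert evaluate_gpr(rule, raised) >= before


class TestValidation:
    def test_undeclared_gene_rejected(self):
        data = {
            "metabolites": [{"id": "A[c]"}],
            "reactions": [
                {"id": "R1", "stoich": {"A[c]": -1.0}, "gpr": "ghost"}
            ],
            "genes": [],
            "objective_id": "",
            "atp_demand_id": "",
        }
        with pytest.raises(ModelValidationError, match="ghost"):
            model_from_dict(data)

    def test_duplicate_ids_rejected(self):
        m = MetabolicModel(
            metabolites=[Metabolite(id="A[c]"), Metabolite(id="A[c]")],
            reactions=[Reaction(id="R", stoich={"A[c]": 1.0})],
        )
        with pytest.raises(ModelValidationError, match="duplicate"):
            m.validate()

    def test_exchange_must_touch_one_metabolite(self):
        m = MetabolicModel(
            metabolites=[Metabolite(id="A[c]"), Metabolite(id="B[c]")],
            reactions=[
                Reaction(id="EX", stoich={"A[c]": -1.0, "B[c]": 1.0},
                         is_exchange=True)
            ],
        )
        with pytest.raises(ModelValidationError, match="exactly one"):
            m.validate()

    def test_bounds_order_enforced(self):
        m = MetabolicModel(
            metabolites=[Metabolite(id="A[c]")],
            reactions=[Reaction(id="R", stoich={"A[c]": 1.0}, lb=5, ub=1)],
        )
        with pytest.raises(ModelValidationError, match="lb"):
            m.validate()

    def test_compartment_from_id_suffix(self):
        assert Metabolite(id="mev1[c]").compartment == "c"
        assert Metabolite(id="5pmev[x]").compartment == "x"

    def test_dead_end_detection(self):
        m = MetabolicModel(
            metabolites=[Metabolite(id="A[c]"), Metabolite(id="B[c]"),
                         Metabolite(id="D[c]")],
            reactions=[
                Reaction(id="EX_A", stoich={"A[c]": -1.0}, lb=-5,
                         is_exchange=True),
                Reaction(id="R1", stoich={"A[c]": -1.0, "B[c]": 1.0}),
                Reaction(id="R2", stoich={"B[c]": -1.0, "D[c]": 1.0}),
            ],
        )
        assert m.dead_end_metabolites() == ["D[c]"]

    def test_toy_network_has_no_dead_ends(self, toy_model):
        assert toy_model.dead_end_metabolites() == []


class TestIO:
    def test_round_trip_identity(self, tmp_path, toy_model):
        p1 = tmp_path / "m1.json"
        p2 = tmp_path / "m2.json"
        write_model(toy_model, p1)
        write_model(load_model(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_round_trip_preserves_structure(self, tmp_path, chain):
        path = tmp_path / "chain.json"
        write_model(chain, path)
        loaded = load_model(path)
        assert model_to_dict(loaded) == model_to_dict(chain)
        assert len(loaded.metabolites) == 2
        assert len(loaded.reactions) == 3

    def test_parse_error_names_problem(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ModelValidationError, match="not valid JSON"):
            load_model(path)

    def test_stoichiometric_matrix_shape(self, toy_model):
        S = toy_model.stoichiometric_matrix()
        assert S.shape == (len(toy_model.metabolites), len(toy_model.reactions))
        assert S.loc["mev1[c]", "MEV1"] == 1.0
        assert S.loc["accoa[c]", "MEV1"] == -2.0


class TestSplitReversible:
    def test_bound_transcription(self):
        m = MetabolicModel(
            metabolites=[Metabolite(id="A[c]"), Metabolite(id="B[c]")],
            reactions=[
                Reaction(id="R1", stoich={"A[c]": -1.0, "B[c]": 1.0},
                         lb=-5, ub=10)
            ],
        )
        out = split_reversible(m)
        ids = {r.id: r for r in out.reactions}
        assert set(ids) == {"R1_f", "R1_b"}
        assert (ids["R1_f"].lb, ids["R1_f"].ub) == (0.0, 10.0)
        assert (ids["R1_b"].lb, ids["R1_b"].ub) == (0.0, 5.0)
        assert ids["R1_b"].stoich == {"A[c]": 1.0, "B[c]": -1.0}

    def test_irreversible_model_unchanged(self, chain):
        chain.reaction("EX_A").lb = 0.0  # make fully irreversible
        out = split_reversible(chain)
        assert out.reaction_ids == chain.reaction_ids

    def test_fba_equivalence_on_random_networks(self, rng):
        """Splitting preserves the optimal objective of any LP."""
        for _ in range(25):
            model = random_network(rng)
            opt_orig, _ = fba(model)
            opt_split, _ = fba(split_reversible(model))
            assert opt_split == pytest.approx(opt_orig, abs=1e-7)
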