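"""Knockout scans, effective scores, and the reaction-removal oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from senflux.constraints import ExpressionProfile, KineticTable, MediumSpec
from senflux.diffflux import DiffResult
from senflux.knockout import (
    KnockoutMatrix,
    effective_scores,
    gene_ko_matrix,
    meta_scores,
    metabolite_ko_matrix,
    norm_background_p,
    score_table_with_p,
)
from senflux.network import (
    MetabolicModel,
    Metabolite,
    Reaction,
    evaluate_gpr,
    parse_gpr,
)
from senflux.solver import (
    FLUX_ZERO_TOL,
    apply_maintenance,
    profile_from_model,
)
from senflux.synthdata import random_abundance, random_network

from ko_oracle import removal_oracle_matrix


def gene_chain(gprs, uptake=10.0, caps=None):
    """Linear A->B->C chain with per-reaction GPR rules."""
    caps = caps or [20.0] * len(gprs)
    mets = [Metabolite(id=f"M{i}[c]") for i in range(len(gprs) + 1)]
    rxns = [Reaction(id="EX_in", stoich={"M0[c]": -1.0}, lb=-uptake, ub=100.0,
                     is_exchange=True)]
    for i, (g, cap) in enumerate(zip(gprs, caps)):
        rxns.append(Reaction(id=f"R{i}",
                             stoich={f"M{i}[c]": -1.0, f"M{i + 1}[c]": 1.0},
                             ub=cap, gpr=g))
    rxns.append(Reaction(id="EX_out", stoich={f"M{len(gprs)}[c]": -1.0},
                         ub=100.0, is_exchange=True))
    genes = sorted({g for rule in gprs for g in
                    (parse_gpr(rule) and _genes(rule) or set())})
    model = MetabolicModel(metabolites=mets, reactions=rxns, genes=genes,
                           objective_id="EX_out")
    model.validate()
    return model


def _genes(rule):
    from senflux.network import gpr_genes

    return gpr_genes(rule)


def constrained_chain(gprs, expr_values, **kw):
    model = gene_chain(gprs, **kw)
    expr = ExpressionProfile(sample_id="s", values=expr_values)
    # apply expression capacity directly (kcat 1)
    for r in model.reactions:
        if r.gpr:
            r.ub = min(r.ub, evaluate_gpr(r.gpr, expr_values))
    maintained, flags = apply_maintenance(model)
    baseline = profile_from_model(maintained, "s", flags)
    return maintained, baseline, expr


class TestGeneKO:
    def test_bottleneck_gene_kills_chain(self):
        maintained, baseline, expr = constrained_chain(
            ["gA", "gB"], {"gA": 5.0, "gB": 8.0}
        )
        km = gene_ko_matrix(maintained, baseline, expr)
        row = km.effects.loc["gA"]
        assert (row[["R0", "R1", "EX_out"]] == -1).all()

    def test_expressed_isozyme_rescues(self):
        maintained, baseline, expr = constrained_chain(
            ["gA or gC", "gB"], {"gA": 5.0, "gB": 8.0, "gC": 5.0}
        )
        km = gene_ko_matrix(maintained, baseline, expr)
        # gA alone cannot block R0: gC carries it
        assert (km.effects.loc["gA"] <= 0).all()
        assert (km.effects.loc["gA"][["R1", "EX_out"]] == 0).all()

    def test_transport_columns_dropped(self, toy_model, kinetics, medium,
                                       cc_profiles):
        from senflux.solver import constrained_sample_model

        e = cc_profiles[0]
        rm, flags = constrained_sample_model(toy_model, e, kinetics, medium)
        baseline = profile_from_model(rm, e.sample_id, flags)
        km = gene_ko_matrix(rm, baseline, e, genes=["g_mev1"])
        assert not any(c.startswith("T_") for c in km.reactions)
        assert (km.effects.loc["g_mev1", ["MEV2", "LIP1", "BIOMASS"]] == -1).all()


class TestMetaboliteKO:
    def test_intermediate_removal_severs_chain(self):
        maintained, baseline, _ = constrained_chain(
            ["gA", "gB"], {"gA": 5.0, "gB": 8.0}
        )
        km = metabolite_ko_matrix(maintained, baseline, metabolites=["M1[c]"])
        assert (km.effects.loc["M1[c]", ["R0", "R1", "EX_out"]] == -1).all()

    def test_dead_end_metabolite_is_noop(self):
        maintained, baseline, _ = constrained_chain(
            ["gA"], {"gA": 5.0}
        )
        maintained.metabolites.append(Metabolite(id="Z[c]"))
        maintained.reactions.append(
            Reaction(id="RZ", stoich={"Z[c]": 1.0}, ub=0.0)
        )
        base2 = profile_from_model(maintained, "s")
        km = metabolite_ko_matrix(maintained, base2, metabolites=["Z[c]"])
        assert (km.effects.loc["Z[c]"] == 0).all()


class TestRemovalOracle:
    """Bound-zeroing knockouts must equal physically deleting the
    affected reactions and re-solving (independent dense-LP oracle)."""

    @pytest.mark.parametrize("n_networks", [25])
    def test_gene_and_metabolite_ko_match_oracle(self, rng, n_networks):
        for _ in range(n_networks):
            model = random_network(rng)
            abundance = random_abundance(model, rng)
            for r in model.reactions:
                if r.gpr:
                    cap = evaluate_gpr(r.gpr, abundance)
                    r.ub = min(r.ub, cap)
                    if r.lb < 0:
                        r.lb = max(r.lb, -cap)
            maintained, flags = apply_maintenance(model)
            baseline = profile_from_model(maintained, "s", flags)
            expr = ExpressionProfile(sample_id="s", values=abundance)
            km_g = gene_ko_matrix(maintained, baseline, expr)
            km_m = metabolite_ko_matrix(maintained, baseline)
            for km, kind in ((km_g, "gene"), (km_m, "metabolite")):
                oracle = removal_oracle_matrix(maintained, baseline, expr, kind)
                pd.testing.assert_frame_equal(km.effects, oracle)


def ternary_matrix(rows, reactions, entities):
    return KnockoutMatrix(
        entity_kind="gene",
        effects=pd.DataFrame(rows, index=entities, columns=reactions,
                             dtype=int),
    )


def diff_table(effects, ps, reactions, kind="case_control"):
    table = pd.DataFrame(
        {"effect": effects, "se": 0.1, "p": ps, "fdr": ps,
         "mean_case": 1.0, "mean_control": 1.0},
        index=reactions,
    )
    return DiffResult(study_id="s", table=table, kind=kind, n_case=5,
                      n_control=5)


class TestEffectiveScores:
    def test_no_significant_reactions_all_zero(self):
        km = ternary_matrix([[-1, 1], [1, 0]], ["R0", "R1"], ["a", "b"])
        diff = diff_table([2.0, -2.0], [0.5, 0.9], ["R0", "R1"])
        est = effective_scores(km, diff)
        assert (est.table["score"] == 0).all()

    def test_term_by_term_product(self):
        km = ternary_matrix([[-1, -1, 1]], ["R0", "R1", "R2"], ["a"])
        diff = diff_table([-1.0, -1.0, 1.0], [0.001] * 3, ["R0", "R1", "R2"])
        est = effective_scores(km, diff)
        assert est.table.loc["a", "score"] == 3.0

    def test_magnitude_filter_applies(self):
        km = ternary_matrix([[-1, -1]], ["R0", "R1"], ["a"])
        # R1 significant but |lfc| below 0.5: excluded
        diff = diff_table([-1.0, -0.3], [0.001, 0.001], ["R0", "R1"])
        est = effective_scores(km, diff)
        assert est.table.loc["a", "score"] == 1.0

    def test_antisymmetric_under_flux_sign_flip(self):
        km = ternary_matrix([[-1, 0, 1], [1, -1, 0]],
                            ["R0", "R1", "R2"], ["a", "b"])
        eff = [-1.0, 2.0, -0.8]
        d1 = diff_table(eff, [0.001] * 3, ["R0", "R1", "R2"])
        d2 = diff_table([-e for e in eff], [0.001] * 3, ["R0", "R1", "R2"])
        s1 = effective_scores(km, d1).table["score"]
        s2 = effective_scores(km, d2).table["score"]
        np.testing.assert_array_equal(s1.to_numpy(), -s2.to_numpy())

    def test_scores_are_integers(self, rng):
        n_r, n_e = 30, 12
        km = ternary_matrix(rng.integers(-1, 2, size=(n_e, n_r)),
                            [f"R{i}" for i in range(n_r)],
                            [f"e{i}" for i in range(n_e)])
        diff = diff_table(rng.normal(0, 2, n_r), rng.uniform(size=n_r),
                          [f"R{i}" for i in range(n_r)])
        scores = effective_scores(km, diff).table["score"]
        assert np.array_equal(scores, scores.round())

    def test_bad_thresholds_rejected(self):
        km = ternary_matrix([[1]], ["R0"], ["a"])
        diff = diff_table([1.0], [0.01], ["R0"])
        with pytest.raises(ValueError):
            effective_scores(km, diff, p_thresh=1.5)
        with pytest.raises(ValueError):
            effective_scores(km, diff, lfc_thresh=-1.0)

    def test_timeseries_uses_fdr_rule(self):
        km = ternary_matrix([[-1, -1]], ["R0", "R1"], ["a"])
        # small slopes; R0 significant by FDR
        diff = diff_table([-0.05, -0.04], [0.001, 0.8], ["R0", "R1"],
                          kind="timeseries")
        est = effective_scores(km, diff)
        assert est.table.loc["a", "score"] == 1.0


class TestNormBackground:
    def test_score_at_mean_gives_p_one(self):
        scores = np.concatenate([[5.0], np.linspace(0, 10, 20)])
        p = norm_background_p(scores)
        assert p[0] == pytest.approx(1.0)

    def test_far_outlier_is_tiny(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 100), [5.5]])
        p = norm_background_p(scores)
        assert p[-1] < 1e-5

    def test_calibrated_on_normal_scores(self, rng):
        scores = rng.normal(0, 1, 2000)
        p = norm_background_p(scores)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_degenerate_background_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            norm_background_p(np.zeros(20))

    def test_needs_ten_entities(self):
        with pytest.raises(ValueError):
            norm_background_p(np.arange(5.0))


class TestMetaScores:
    def _table(self, scores, rng):
        idx = [f"e{i}" for i in range(len(scores))]
        from senflux.knockout import EffectiveScoreTable

        est = EffectiveScoreTable(
            entity_kind="gene",
            table=pd.DataFrame({"score": scores}, index=idx),
        )
        return score_table_with_p(est)

    def test_identical_tables_preserve_score(self, rng):
        t = self._table(np.concatenate([[8.0], rng.normal(0, 1, 20)]), rng)
        meta = meta_scores([t, t, t])
        assert meta.table.loc["e0", "meta_score"] == pytest.approx(8.0)
        assert meta.table.loc["e0", "meta_fdr"] < 0.05

    def test_opposite_studies_cancel(self, rng):
        base = np.concatenate([[6.0], rng.normal(0, 1, 20)])
        t1 = self._table(base, rng)
        t2 = self._table(-base, rng)
        meta = meta_scores([t1, t2])
        assert meta.table.loc["e0", "meta_score"] == pytest.approx(0.0)
        assert meta.table.loc["e0", "meta_p"] == pytest.approx(1.0, abs=1e-6)

    def test_needs_two_studies(self, rng):
        t = self._table(np.arange(15.0), rng)
        with pytest.raises(ValueError):
            meta_scores([t])
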