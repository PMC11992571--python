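"""Differential flux statistics: fold changes, slopes, FDR, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from senflux.diffflux import (
    bh_fdr,
    case_control_diff,
    spearman_trajectory,
    timeseries_diff,
)


def hand_bh(pvalues):
    """Independent Benjamini–Hochberg step-up computed by hand."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


def make_fluxes(case, ctrl, n_reactions=1, prefix="R"):
    """reactions x samples frame from per-group per-reaction arrays."""
    case = np.atleast_2d(case)
    ctrl = np.atleast_2d(ctrl)
    cols = [f"p{i}" for i in range(ctrl.shape[1])] + [
        f"s{i}" for i in range(case.shape[1])
    ]
    data = np.hstack([ctrl, case])
    return (
        pd.DataFrame(data, index=[f"{prefix}{i}" for i in range(case.shape[0])],
                     columns=cols),
        {c: ("proliferative" if c.startswith("p") else "senescent") for c in cols},
    )


class TestCaseControl:
    def test_identical_means_zero_lfc(self):
        fluxes, groups = make_fluxes([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        res = case_control_diff(fluxes, groups)
        assert res.table["effect"].iloc[0] == pytest.approx(0.0)

    def test_halved_flux_gives_minus_one(self):
        fluxes, groups = make_fluxes(
            [[5.0, 5.0, 5.0]], [[10.0, 10.0, 10.0]]
        )
        res = case_control_diff(fluxes, groups)
        assert res.table["effect"].iloc[0] == pytest.approx(-1.0, abs=1e-4)

    def test_label_swap_negates_lfc_exactly(self, rng):
        data = rng.lognormal(1.0, 0.5, size=(30, 10))
        cols = [f"x{i}" for i in range(10)]
        fluxes = pd.DataFrame(data, columns=cols)
        g1 = {c: ("proliferative" if i < 5 else "senescent")
              for i, c in enumerate(cols)}
        g2 = {c: ("senescent" if i < 5 else "proliferative")
              for i, c in enumerate(cols)}
        r1 = case_control_diff(fluxes, g1)
        r2 = case_control_diff(fluxes, g2)
        np.testing.assert_allclose(
            r1.table["effect"], -r2.table["effect"], atol=1e-12
        )
        np.testing.assert_allclose(r1.table["p"], r2.table["p"], atol=1e-12)

    def test_constant_zero_reaction(self):
        fluxes, groups = make_fluxes([[0.0, 0.0]], [[0.0, 0.0]])
        res = case_control_diff(fluxes, groups)
        assert res.table["effect"].iloc[0] == 0.0
        assert res.table["p"].iloc[0] == 1.0

    def test_small_group_rejected(self):
        fluxes, groups = make_fluxes([[1.0]], [[1.0, 2.0]])
        with pytest.raises(ValueError, match=">=2 samples"):
            case_control_diff(fluxes, groups)

    def test_planted_effect_power(self, rng):
        """A 2x knockdown at n=5v5, noise sd 0.1, is nearly always
        detected at FDR < 0.05 (Monte-Carlo power over 200 replicates,
        with 50 null reactions alongside)."""
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            null = rng.lognormal(1.0, 0.1, size=(50, 10))
            ctrl = 4.0 * rng.lognormal(0.0, 0.1, size=(1, 5))
            case = 2.0 * rng.lognormal(0.0, 0.1, size=(1, 5))
            fluxes = pd.DataFrame(
                np.vstack([np.hstack([ctrl, case]), null]),
                index=[f"R{i}" for i in range(51)],
                columns=[f"p{i}" for i in range(5)] + [f"s{i}" for i in range(5)],
            )
            groups = {c: ("proliferative" if c.startswith("p") else "senescent")
                      for c in fluxes.columns}
            res = case_control_diff(fluxes, groups)
            if res.table.loc["R0", "fdr"] < 0.05:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_null_type_one_error_calibrated(self, rng):
        """Under the null, about 5% of reactions reach p < 0.05."""
        data = rng.lognormal(1.0, 0.4, size=(2000, 10))
        cols = [f"x{i}" for i in range(10)]
        fluxes = pd.DataFrame(data, columns=cols)
        groups = {c: ("proliferative" if i < 5 else "senescent")
                  for i, c in enumerate(cols)}
        res = case_control_diff(fluxes, groups)
        frac = float((res.table["p"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07


class TestTimeseries:
    def test_exact_linear_fit(self):
        passages = {f"s{i}": p for i, p in enumerate([1, 2, 3, 4, 5])}
        fluxes = pd.DataFrame(
            {f"s{i}": [10.0 - 0.2 * p] for i, p in enumerate([1, 2, 3, 4, 5])},
            index=["R0"],
        )
        res = timeseries_diff(fluxes, passages)
        assert res.table["effect"].iloc[0] == pytest.approx(-0.2)
        assert res.table["p"].iloc[0] < 1e-10

    def test_passage_shift_invariance(self, rng):
        y = rng.normal(5.0, 1.0, size=(20, 6))
        cols = [f"s{i}" for i in range(6)]
        fluxes = pd.DataFrame(y, columns=cols)
        p1 = {c: i for i, c in enumerate(cols)}
        p2 = {c: i + 12 for i, c in enumerate(cols)}  # relabelled passages
        r1 = timeseries_diff(fluxes, p1)
        r2 = timeseries_diff(fluxes, p2)
        np.testing.assert_allclose(r1.table["effect"], r2.table["effect"],
                                   atol=1e-12)

    def test_constant_passages_rejected(self):
        fluxes = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]})
        with pytest.raises(ValueError, match="distinct passage"):
            timeseries_diff(fluxes, {"a": 5, "b": 5, "c": 5})

    def test_null_pvalues_uniform(self, rng):
        """White-noise fluxes give uniform slope p-values (KS check)."""
        y = rng.normal(10.0, 1.0, size=(2000, 9))
        cols = [f"s{i}" for i in range(9)]
        fluxes = pd.DataFrame(y, columns=cols)
        res = timeseries_diff(fluxes, {c: i for i, c in enumerate(cols)})
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01


class TestSpearman:
    def test_perfect_antirank(self):
        rho, p = spearman_trajectory([9, 7, 5, 3, 1], [1, 2, 3, 4, 5])
        assert rho == pytest.approx(-1.0)
        assert p < 0.05

    def test_independent_values_near_zero_on_average(self, rng):
        rhos = [
            spearman_trajectory(rng.normal(size=12), np.arange(12))[0]
            for _ in range(300)
        ]
        assert abs(np.mean(rhos)) < 0.05

    def test_needs_four_points(self):
        with pytest.raises(ValueError):
            spearman_trajectory([1, 2, 3], [1, 2, 3])


class TestBH:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize(
        "p", [[0.5], [1.0, 1.0, 1.0], [0.001, 0.5, 0.9, 0.02]]
    )
    def test_matches_independent_oracle(self, p):
        np.testing.assert_allclose(bh_fdr(p), hand_bh(p), atol=1e-12)

    def test_random_inputs_match_oracle(self, rng):
        p = rng.uniform(size=500)
        np.testing.assert_allclose(bh_fdr(p), hand_bh(p), atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = np.sort(rng.uniform(size=200))
        adj = bh_fdr(p)
        assert (np.diff(adj) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
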