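"""Regulation, deregulation and decorrelation scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest

from joda.pathway import build_model
from joda.scoring import (
    AlignmentError,
    average_deregulation,
    decorrelation_scores,
    deregulation_scores,
    regulation_scores,
    sort_deregulation_list,
)

from conftest import random_topology, reachability_oracle


def _p_matrix(values, genes, experiments):
    return pd.DataFrame(values, index=genes, columns=experiments, dtype=float)


class TestRegulationScores:
    def test_identity_model_returns_signed_probabilities(self, model_healthy):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(10)]
        P = _p_matrix(rng.uniform(-1, 1, (10, 3)), genes,
                      list(model_healthy.experiments))
        R = regulation_scores(P, model_healthy)
        np.testing.assert_allclose(R.to_numpy(), P.to_numpy())

    def test_average_over_upstream_and_self(self, model_damaged):
        P = _p_matrix([[0.6, 0.8, 0.0]], ["g"],
                      list(model_damaged.experiments))
        R = regulation_scores(P, model_damaged)
        # RelA is affected by its own and ATM's perturbation
        assert R.loc["g", "RelA"] == pytest.approx(0.7)

    def test_matches_reachability_and_mean_oracle(self):
        rng = np.random.default_rng(17)
        topo = random_topology(rng, 6, 0.35, population="d")
        model = build_model(topo)
        genes = [f"g{i}" for i in range(50)]
        P = _p_matrix(rng.uniform(-1, 1, (50, 6)), genes,
                      list(model.experiments))
        R = regulation_scores(P, model)
        reach = reachability_oracle(topo)
        for v in topo.regulators:
            upstream = [
                f"d:{u}" for u in topo.regulators if v in reach[u]
            ]
            expected = P[upstream].to_numpy().mean(axis=1)
            np.testing.assert_allclose(R[v].to_numpy(), expected)

    def test_missing_probabilities_dropped_from_average(self, model_damaged):
        P = _p_matrix([[np.nan, 0.8, 0.2]], ["g"],
                      list(model_damaged.experiments))
        R = regulation_scores(P, model_damaged)
        assert R.loc["g", "RelA"] == pytest.approx(0.8)

    def test_all_missing_gives_missing_score_with_warning(self, model_healthy):
        P = _p_matrix([[np.nan, 0.5, 0.5]], ["g"],
                      list(model_healthy.experiments))
        with pytest.warns(UserWarning, match="missing"):
            R = regulation_scores(P, model_healthy)
        assert np.isnan(R.loc["g", "ATM"])


class TestDeregulationScores:
    def _r(self, value):
        return pd.DataFrame({"v": [value]}, index=["g"], dtype=float)

    def test_activation_switch_is_strongly_negative(self):
        D = deregulation_scores(self._r(-0.9), self._r(0.8))
        assert D.loc["g", "v"] == pytest.approx(-1.7)

    def test_identical_regulation_gives_zero(self):
        rng = np.random.default_rng(1)
        R = pd.DataFrame(rng.uniform(-1, 1, (20, 3)),
                         index=[f"g{i}" for i in range(20)],
                         columns=["a", "b", "c"])
        assert (deregulation_scores(R, R.copy()) == 0).all().all()

    def test_extreme_bound_attained(self):
        D = deregulation_scores(self._r(1.0), self._r(-1.0))
        assert D.loc["g", "v"] == pytest.approx(2.0)

    def test_misalignment_lists_offending_ids(self):
        a = pd.DataFrame({"v": [0.0]}, index=["g1"])
        b = pd.DataFrame({"v": [0.0]}, index=["g2"])
        with pytest.raises(AlignmentError, match="g1.*g2"):
            deregulation_scores(a, b)


class TestScoreBounds:
    def test_exhaustive_grid_respects_and_attains_bounds(
        self, model_healthy, model_damaged
    ):
        # all +/-1/0 signed-probability assignments over both populations'
        # three experiments, one grid point per pseudo-gene
        grid = np.array(
            list(itertools.product((-1.0, 0.0, 1.0), repeat=6))
        )
        genes = [f"c{i}" for i in range(len(grid))]
        P_h = _p_matrix(grid[:, :3], genes, list(model_healthy.experiments))
        P_d = _p_matrix(grid[:, 3:], genes, list(model_damaged.experiments))
        R_h = regulation_scores(P_h, model_healthy)
        R_d = regulation_scores(P_d, model_damaged)
        D = deregulation_scores(R_d, R_h)
        for R in (R_h, R_d):
            assert R.to_numpy().min() >= -1 and R.to_numpy().max() <= 1
        assert R_h.to_numpy().max() == pytest.approx(1.0)
        assert D.to_numpy().min() >= -2 and D.to_numpy().max() <= 2
        assert D.to_numpy().max() == pytest.approx(2.0)
        assert D.to_numpy().min() == pytest.approx(-2.0)

    def test_population_swap_negates_deregulation(self, model_damaged,
                                                  model_healthy):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(30)]
        P_h = _p_matrix(rng.uniform(-1, 1, (30, 3)), genes,
                        list(model_healthy.experiments))
        P_d = _p_matrix(rng.uniform(-1, 1, (30, 3)), genes,
                        list(model_damaged.experiments))
        R_h = regulation_scores(P_h, model_healthy)
        R_d = regulation_scores(P_d, model_damaged)
        D = deregulation_scores(R_d, R_h)
        D_swapped = deregulation_scores(R_h, R_d)
        np.testing.assert_array_equal(D.to_numpy(), -D_swapped.to_numpy())


class TestDecorrelationScores:
    def test_subtraction_direction(self):
        # regulator/gene perfectly correlated in healthy, strongly
        # anticorrelated in damaged: score close to corr_h - corr_d
        t = np.arange(6, dtype=float)
        expr_h = pd.DataFrame([t, 2 * t + 1], index=["r", "g"])
        expr_d = pd.DataFrame([t, -t], index=["r", "g"])
        S = decorrelation_scores(expr_h, expr_d, ["r"])
        assert S.loc["g", "r"] == pytest.approx(1.0 - (-1.0))

    def test_identical_populations_give_zero(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(8, 1, (10, 6)),
                            index=[f"g{i}" for i in range(10)])
        S = decorrelation_scores(expr, expr.copy(), ["g0", "g1"])
        np.testing.assert_allclose(S.to_numpy(), 0.0, atol=1e-12)

    def test_matches_sum_formula_pearson_oracle(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(20)]
        expr_h = pd.DataFrame(rng.normal(0, 1, (20, 6)), index=genes)
        expr_d = pd.DataFrame(rng.normal(0, 1, (20, 6)), index=genes)
        regs = ["g0", "g5"]
        S = decorrelation_scores(expr_h, expr_d, regs)

        def pearson(a, b):
            n = len(a)
            num = n * (a * b).sum() - a.sum() * b.sum()
            den = np.sqrt(n * (a**2).sum() - a.sum() ** 2) * np.sqrt(
                n * (b**2).sum() - b.sum() ** 2
            )
            return num / den

        for r in regs:
            for g in genes:
                expected = pearson(
                    expr_h.loc[r].to_numpy(), expr_h.loc[g].to_numpy()
                ) - pearson(
                    expr_d.loc[r].to_numpy(), expr_d.loc[g].to_numpy()
                )
                assert S.loc[g, r] == pytest.approx(expected, abs=1e-12)

    def test_insufficient_replication_raises(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["r"])
        with pytest.raises(ValueError, match="insufficient replication"):
            decorrelation_scores(expr, expr, ["r"])

    def test_zero_variance_profile_warns_and_is_missing(self):
        genes = ["r", "flat", "ok"]
        expr_h = pd.DataFrame(
            [[1, 2, 3, 4], [5, 5, 5, 5], [2, 1, 4, 3]], index=genes,
            dtype=float,
        )
        expr_d = pd.DataFrame(
            np.random.default_rng(5).normal(0, 1, (3, 4)), index=genes
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            S = decorrelation_scores(expr_h, expr_d, ["r"])
        assert np.isnan(S.loc["flat", "r"])


class TestSortedLists:
    def test_decreasing_order(self):
        D = pd.DataFrame(
            {"v": [-1.7, -0.9, 0.0, 0.2]}, index=["g1", "g2", "g3", "g4"]
        )
        ranked = sort_deregulation_list(D, "v")
        assert list(ranked.index) == ["g4", "g3", "g2", "g1"]

    def test_ties_break_lexicographically(self):
        D = pd.DataFrame({"v": [0.5] * 4}, index=["d", "b", "a", "c"])
        assert list(sort_deregulation_list(D, "v").index) == list("abcd")

    def test_agrees_with_sort_oracle(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(40)]
        D = pd.DataFrame({"v": rng.normal(0, 1, 40)}, index=genes)
        ranked = sort_deregulation_list(D, "v")
        expected = sorted(genes, key=lambda g: (-D.loc[g, "v"], g))
        assert list(ranked.index) == expected

    def test_average_deregulation_is_row_mean(self):
        D = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, -1.0]},
                         index=["g1", "g2"])
        avg = average_deregulation(D)
        assert avg["g1"] == pytest.approx(0.5)
        assert avg["g2"] == pytest.approx(-0.5)
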