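"""Belief-based two-Gaussian mixture: EM behaviour and signed probabilities."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from joda.mixture import (
    BeliefGaussianMixture,
    BeliefSet,
    InsufficientDataError,
    fit_belief_mixture,
    signed_probabilities,
)


def plain_em_oracle(x, means, sds, weights, max_iter=1000, tol=1e-8):
    """Independent textbook unsupervised two-component EM (no priors)."""
    def estep(means, sds, weights):
        dens = np.column_stack(
            [weights[j] * norm.pdf(x, means[j], sds[j]) for j in (0, 1)]
        )
        tot = np.maximum(dens.sum(axis=1), np.finfo(float).tiny)
        return dens / tot[:, None], float(np.log(tot).sum())

    resp, ll = estep(means, sds, weights)
    for _ in range(max_iter):
        nk = np.maximum(resp.sum(axis=0), np.finfo(float).tiny)
        weights = nk / nk.sum()
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        if var[1] < var[0]:
            var[:] = (nk * var).sum() / nk.sum()
        var = np.maximum(var, 1e-6)
        sds = np.sqrt(var)
        resp, new_ll = estep(means, sds, weights)
        if new_ll - ll <= tol * max(abs(ll), 1.0):
            break
        ll = new_ll
    return resp, means, sds, weights


def _fixed_fit(means, sds, weights, differential=1):
    est = BeliefGaussianMixture()
    est.means_ = np.asarray(means, float)
    est.sds_ = np.asarray(sds, float)
    est.weights_ = np.asarray(weights, float)
    est.differential_ = differential
    return est


class TestPosteriors:
    def test_belief_dominates_at_equal_densities(self):
        # symmetric components: densities cancel at 0, posterior = belief
        est = _fixed_fit([-1.0, 1.0], [0.5, 0.5], [0.7, 0.3])
        post = est.predict_proba([0.0], beliefs=[0.95])
        assert post[0] == pytest.approx(0.95, abs=1e-12)

    def test_unlabelled_at_equal_densities_gets_mixing_proportion(self):
        est = _fixed_fit([-1.0, 1.0], [0.5, 0.5], [0.5, 0.5])
        assert est.predict_proba([0.0])[0] == pytest.approx(0.5, abs=1e-12)

    def test_missing_ratio_gives_missing_posterior(self):
        est = _fixed_fit([0.0, 0.0], [0.2, 2.0], [0.9, 0.1])
        post = est.predict_proba([np.nan, 1.0])
        assert np.isnan(post[0]) and np.isfinite(post[1])


class TestEMFit:
    def test_recovers_planted_standard_deviations(self):
        rng = np.random.default_rng(1)
        x = np.concatenate(
            [rng.normal(0, 0.2, 1800), rng.normal(0, 2.0, 200)]
        )
        est = BeliefGaussianMixture().fit(x)
        d, u = est.differential_, 1 - est.differential_
        assert est.sds_[u] == pytest.approx(0.2, rel=0.25)
        assert est.sds_[d] == pytest.approx(2.0, rel=0.25)
        # at ratio 3.0 the true-parameter posterior is ~1; the fit agrees
        true_post = (0.1 * norm.pdf(3.0, 0, 2.0)) / (
            0.1 * norm.pdf(3.0, 0, 2.0) + 0.9 * norm.pdf(3.0, 0, 0.2)
        )
        assert true_post > 0.999
        assert est.predict_proba([3.0])[0] > 0.95

    @pytest.mark.parametrize("data", [
        np.random.default_rng(0).normal(0, 1, 500),
        np.concatenate([np.random.default_rng(1).normal(-2, 0.3, 100),
                        np.random.default_rng(2).normal(2, 0.3, 400)]),
        np.random.default_rng(3).standard_t(df=2, size=300),
        np.concatenate([np.full(250, 0.5), [0.49, 0.51] * 10]),
        np.random.default_rng(4).uniform(-5, 5, 1000),
    ], ids=["gaussian", "bimodal", "heavy-tail", "near-constant", "uniform"])
    def test_objective_never_decreases(self, data):
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = BeliefGaussianMixture().fit(data)
        assert (np.diff(est.loglik_trace_) >= -1e-9).all()

    def test_empty_beliefs_equal_plain_unsupervised_em(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0, 0.3, 400), rng.normal(0, 1.5, 100)])
        est = BeliefGaussianMixture(weight_prior=0.0).fit(x)
        means0, sds0, weights0 = est._initial_params(x)
        resp, *_ = plain_em_oracle(x, means0, sds0, weights0)
        np.testing.assert_allclose(
            est.responsibilities_, resp, atol=1e-10
        )

    def test_labelled_points_steer_the_fit(self):
        # beliefs pull borderline points into the differential component
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 0.3, 400), rng.normal(0, 1.5, 100)])
        bel = np.full(x.size, np.nan)
        bel[450:470] = 0.95
        sup = BeliefGaussianMixture().fit(x, bel)
        uns = BeliefGaussianMixture().fit(x)
        labelled_post = sup.responsibilities_[450:470, sup.differential_]
        unlabelled_post = uns.responsibilities_[450:470, uns.differential_]
        assert labelled_post.mean() > unlabelled_post.mean()

    def test_too_few_values_raises(self):
        with pytest.raises(InsufficientDataError):
            BeliefGaussianMixture().fit(np.arange(10.0))

    def test_belief_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            BeliefGaussianMixture().fit(np.arange(30.0), beliefs=[0.95] * 5)

    def test_differential_component_has_larger_variance(self):
        rng = np.random.default_rng(13)
        x = np.concatenate([rng.normal(0, 0.2, 900), rng.normal(0, 3.0, 100)])
        est = BeliefGaussianMixture().fit(x)
        assert est.sds_[est.differential_] == est.sds_.max()


class TestFitBeliefMixture:
    def test_unknown_belief_genes_warned_and_ignored(self):
        rng = np.random.default_rng(2)
        ratios = pd.Series(rng.normal(0, 1, 50),
                           index=[f"g{i}" for i in range(50)])
        beliefs = BeliefSet("h", "ATM", {"g1": 0.95, "nope": 0.95})
        with pytest.warns(UserWarning, match="absent"):
            fit = fit_belief_mixture(ratios, beliefs, experiment="h:ATM")
        assert fit.posterior.index.equals(ratios.index)

    def test_missing_ratios_excluded_and_propagated(self):
        rng = np.random.default_rng(8)
        ratios = pd.Series(rng.normal(0, 1, 40),
                           index=[f"g{i}" for i in range(40)])
        ratios.iloc[[3, 17]] = np.nan
        fit = fit_belief_mixture(ratios)
        assert fit.posterior.isna().sum() == 2
        assert fit.posterior.iloc[3] != fit.posterior.iloc[3]  # NaN

    def test_belief_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="strictly"):
            BeliefSet("h", "ATM", {"g1": 1.0})


class TestSignedProbabilities:
    @pytest.mark.parametrize("ratio,expected", [
        (1.2, 0.9), (-1.2, -0.9), (0.0, 0.0),
    ])
    def test_sign_convention(self, ratio, expected):
        genes = [f"g{i}" for i in range(3)]
        fit = fit_belief_mixture(
            pd.Series(np.linspace(-2, 2, 30),
                      index=[f"x{i}" for i in range(30)])
        )
        fit.posterior = pd.Series([0.9, 0.9, 0.9], index=genes)
        ratios = pd.Series([ratio, 0.5, -0.5], index=genes)
        out = signed_probabilities(fit, ratios)
        assert out.iloc[0] == pytest.approx(expected)

    def test_bounds_hold_for_any_input(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            ratios = pd.Series(rng.standard_t(3, 80) * 2,
                               index=[f"g{i}" for i in range(80)])
            fit = fit_belief_mixture(ratios)
            out = signed_probabilities(fit, ratios)
            assert out.abs().max() <= 1.0

    def test_index_mismatch_raises(self):
        ratios = pd.Series(np.linspace(-2, 2, 30),
                           index=[f"g{i}" for i in range(30)])
        fit = fit_belief_mixture(ratios)
        with pytest.raises(ValueError, match="index"):
            signed_probabilities(fit, ratios.iloc[:20])
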