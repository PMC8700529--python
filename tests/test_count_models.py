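import warnings

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import poisson as poisson_dist

import oracles
from aistext.count_models import (
    THETA_CAP,
    fit_hurdle_nb,
    fit_negbin,
    fit_poisson,
    nb_logpmf,
    relative_risk,
    screen_terms_count,
    truncated_nb_logpmf,
    TermWeight,
)
from aistext.dtm import build_dtm
from aistext.preprocess import CleanDocument


class TestPoisson:
    def test_intercept_only_closed_form(self):
        y = np.full(30, 5.0)
        fit = fit_poisson(y)
        assert fit.count_coefs[0] == pytest.approx(np.log(5.0), abs=1e-8)

    def test_saturating_fit_matches_independent_irls(self, rng):
        x = rng.uniform(0, 3, size=200)
        y = rng.poisson(np.exp(0.3 + 0.6 * x)).astype(float)
        fit = fit_poisson(y, x)

        # hand-rolled IRLS for the log-link Poisson GLM
        beta = np.zeros(2)
        X = np.column_stack([np.ones_like(x), x])
        for _ in range(50):
            mu = np.exp(X @ beta)
            W = mu
            z = X @ beta + (y - mu) / mu
            beta = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
        assert np.allclose(fit.count_coefs, beta, atol=1e-6)

    def test_loglik_matches_grid_oracle(self, count_fixture_20):
        y, x = count_fixture_20
        fit = fit_poisson(y, x)
        best, _ = oracles.grid_maximize(
            lambda p: oracles.poisson_loglik(y, x, *p), [(-3, 3), (-3, 3)]
        )
        assert fit.loglik == pytest.approx(best, abs=1e-4)

    def test_loglog_link_transforms_predictor(self, count_fixture_20):
        y, x = count_fixture_20
        fit = fit_poisson(y, x, link="loglog")
        ref = fit_poisson(y, np.log1p(x), link="loglinear")
        assert np.allclose(fit.count_coefs, ref.count_coefs, atol=1e-8)
        assert fit.loglik == pytest.approx(ref.loglik, abs=1e-8)

    def test_constant_predictor_flagged(self):
        fit = fit_poisson(np.array([1.0, 2, 3, 1]), np.full(4, 2.0))
        assert not fit.converged
        assert np.isnan(fit.count_coefs[1])

    def test_non_integer_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_poisson(np.array([1.5, 2.0]), np.array([0.0, 1.0]))


class TestNegBin:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        n = 5000
        x = rng.integers(0, 4, size=n).astype(float)
        mu = np.exp(0.4 + 0.7 * x)
        theta = 1.5
        y = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
        fit = fit_negbin(y, x)
        assert fit.converged
        assert abs(fit.count_coefs[1] - 0.7) < 3 * fit.count_bse[1]
        assert abs(fit.count_coefs[0] - 0.4) < 3 * fit.count_bse[0]
        assert 0.5 * theta < fit.dispersion < 2.0 * theta

    def test_poisson_limit_of_nb_logpmf(self, count_fixture_20):
        y, _ = count_fixture_20
        mu = np.full_like(y, y.mean() + 0.5)
        nb = nb_logpmf(y, mu, 1e8).sum()
        po = poisson_dist.logpmf(y.astype(int), mu).sum()
        assert nb == pytest.approx(po, abs=1e-3)

    def test_intercept_only_loglik_matches_direct_pmf_sum(self):
        y = np.array([0.0] * 19 + [5.0])
        fit = fit_negbin(y)
        direct = nb_logpmf(y, fit.count_mean(), fit.dispersion).sum()
        assert fit.loglik == pytest.approx(direct, abs=1e-6)

    def test_equidispersed_data_caps_theta_with_warning(self):
        rng = np.random.default_rng(3)
        # binomial counts are underdispersed: theta is pushed to infinity
        y = rng.binomial(10, 0.4, size=2000).astype(float)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = fit_negbin(y)
        assert fit.dispersion == THETA_CAP
        assert fit.converged
        assert any("capped" in str(w.message) for w in caught)

    def test_loglik_matches_grid_oracle(self):
        # overdispersed fixture so the dispersion optimum is interior
        rng = np.random.default_rng(15)
        x = rng.integers(0, 4, size=20).astype(float)
        mu = np.exp(0.3 + 0.5 * x)
        y = rng.negative_binomial(1.5, 1.5 / (1.5 + mu)).astype(float)
        fit = fit_negbin(y, x)
        best, _ = oracles.grid_maximize(
            lambda p: oracles.negbin_loglik(y, x, *p), [(-3, 3), (-3, 3), (-4, 4)]
        )
        assert fit.loglik == pytest.approx(best, abs=1e-4)


class TestTruncatedNbLogpmf:
    def test_normalizes_over_positive_support(self):
        ys = np.arange(1, 4000)
        total = np.exp(truncated_nb_logpmf(ys, 2.0, 1.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_exact_rational_arithmetic(self):
        # theta=1 reduces to a geometric distribution: closed form via sympy
        import sympy

        mu, theta = sympy.Rational(2), sympy.Integer(1)
        p = theta / (theta + mu)
        for y in (1, 2, 5, 17):
            f_y = p**theta * (1 - p) ** y  # geometric pmf, exact
            f_0 = p**theta
            exact = float(sympy.log(f_y / (1 - f_0)))
            ours = truncated_nb_logpmf(np.array([y]), 2.0, 1.0)[0]
            assert ours == pytest.approx(exact, abs=1e-12)

    def test_large_theta_approaches_truncated_poisson(self):
        mu = 3.0
        ys = np.arange(1, 20)
        ztp = (
            ys * np.log(mu) - mu - gammaln(ys + 1.0) - np.log1p(-np.exp(-mu))
        )
        assert np.allclose(truncated_nb_logpmf(ys, mu, 1e9), ztp, atol=1e-6)

    def test_zero_outside_support(self):
        with pytest.raises(ValueError):
            truncated_nb_logpmf(np.array([0]), 2.0, 1.0)

    def test_stable_for_tiny_mean(self):
        # f(0) -> 1: the renormalizer 1 - f(0) is tiny but must stay accurate
        val = truncated_nb_logpmf(np.array([1]), 1e-10, 2.0)[0]
        # P(Y=1 | Y>=1) -> 1 as mu -> 0
        assert val == pytest.approx(0.0, abs=1e-6)


class TestHurdle:
    @staticmethod
    def _sim(seed, n=800):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=n).astype(float)
        y = oracles.simulate_hurdle(rng, x, -0.5, 0.8, 0.3, 0.6, 2.0)
        return y.astype(float), x

    def test_loglik_is_sum_of_component_logliks(self):
        y, x = self._sim(1)
        fit = fit_hurdle_nb(y, x)
        zero_ll = oracles.logistic_loglik((y > 0).astype(float), x, *fit.zero_coefs)
        pos = y > 0
        count_ll = oracles.ztnb_loglik(
            y[pos], x[pos], fit.count_coefs[0], fit.count_coefs[1],
            np.log(fit.dispersion),
        )
        assert fit.loglik == pytest.approx(zero_ll + count_ll, abs=1e-8)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        n = 5000
        x = rng.integers(0, 4, size=n).astype(float)
        y = oracles.simulate_hurdle(rng, x, -0.5, 0.8, 0.3, 0.6, 2.0).astype(float)
        fit = fit_hurdle_nb(y, x)
        assert fit.converged
        assert abs(fit.zero_coefs[0] - (-0.5)) < 3 * fit.zero_bse[0]
        assert abs(fit.zero_coefs[1] - 0.8) < 3 * fit.zero_bse[1]
        assert abs(fit.count_coefs[0] - 0.3) < 3 * fit.count_bse[0]
        assert abs(fit.count_coefs[1] - 0.6) < 3 * fit.count_bse[1]

    def test_pmf_normalizes_including_zero_mass(self):
        y, x = self._sim(2, n=300)
        fit = fit_hurdle_nb(y, x)
        total = fit.prob_zero().copy()
        for c in range(1, 4000):
            total += fit.pmf(c)
        assert np.allclose(total, 1.0, atol=1e-8)

    def test_degenerate_outcomes_rejected(self):
        with pytest.raises(ValueError):
            fit_hurdle_nb(np.zeros(10), np.arange(10.0))
        with pytest.raises(ValueError):
            fit_hurdle_nb(np.ones(10), np.arange(10.0))

    def test_aic_identity(self):
        y, x = self._sim(3, n=400)
        fit = fit_hurdle_nb(y, x)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik, abs=1e-10)


class TestRelativeRisk:
    def test_exp_of_slope(self):
        y, x = TestHurdle._sim(4, n=400)
        fit = fit_hurdle_nb(y, x)
        tw = relative_risk(fit, "kw")
        assert tw.weight == pytest.approx(np.exp(fit.count_coefs[1]))
        assert tw.source == "hurdle_count"

    @pytest.mark.parametrize("slope,expected", [(0.0, 1.0), (np.log(2.0), 2.0)])
    def test_slope_to_rr_mapping(self, slope, expected):
        from aistext.count_models import CountModelFit

        fit = CountModelFit(
            "negbin", np.array([0.1, slope]), np.array([0.1, 0.1]),
            np.array([0.5, 0.5]), loglik=-1.0, aic=8.0, converged=True,
            n_obs=10, dispersion=2.0, n_params=3,
        )
        assert relative_risk(fit).weight == pytest.approx(expected)

    def test_non_converged_fit_gives_absent_weight(self):
        fit = fit_poisson(np.array([1.0, 2, 3, 1]), np.full(4, 2.0))
        tw = relative_risk(fit, "const")
        assert tw.is_missing and not tw.converged


class TestScreening:
    @staticmethod
    def _toy_corpus(rng):
        docs = []
        for i in range(300):
            toks = []
            for term, p in (("alpha", 0.5), ("beta", 0.4), ("gamma", 0.3)):
                toks += [term] * rng.binomial(2, p)
            docs.append(CleanDocument(f"d{i}", tuple(toks) or ("alpha",)))
        return build_dtm(docs)

    def test_each_weight_equals_standalone_fit(self, rng):
        dtm = self._toy_corpus(rng)
        y = rng.poisson(2.0, size=300).astype(float)
        weights = screen_terms_count(dtm, y, "poisson_loglinear")
        for w in weights:
            standalone = relative_risk(
                fit_poisson(y, dtm.column(w.term).astype(float)), w.term
            )
            assert w.weight == pytest.approx(standalone.weight, rel=1e-10)

    def test_zero_occurrence_term_gets_absent_weight(self, rng):
        dtm = self._toy_corpus(rng)
        # graft an all-zero column
        import scipy.sparse as sp

        counts = sp.hstack([dtm.counts, sp.csr_matrix((dtm.shape[0], 1), dtype=np.int64)]).tocsr()
        from aistext.dtm import DocumentTermMatrix

        dtm2 = DocumentTermMatrix(dtm.doc_ids, list(dtm.terms) + ["ghost"], counts)
        y = rng.poisson(2.0, size=300).astype(float)
        weights = screen_terms_count(dtm2, y, "poisson_loglinear")
        ghost = [w for w in weights if w.term == "ghost"][0]
        assert ghost.is_missing and not ghost.converged

    def test_vocabulary_permutation_permutes_output(self, rng):
        dtm = self._toy_corpus(rng)
        y = rng.poisson(2.0, size=300).astype(float)
        w1 = {w.term: w.weight for w in screen_terms_count(dtm, y, "poisson_loglinear")}
        perm = [2, 0, 1]
        from aistext.dtm import DocumentTermMatrix

        dtm_p = DocumentTermMatrix(
            dtm.doc_ids, dtm.terms[perm], dtm.dense_counts()[:, perm]
        )
        w2 = {w.term: w.weight for w in screen_terms_count(dtm_p, y, "poisson_loglinear")}
        assert w1 == pytest.approx(w2)

    def test_misaligned_outcome_rejected(self, rng):
        dtm = self._toy_corpus(rng)
        with pytest.raises(ValueError):
            screen_terms_count(dtm, np.ones(5), "poisson_loglinear")
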