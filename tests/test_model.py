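"""Model building blocks: linear predictor, softmax link, multinomial
likelihood with cause aggregation (against an enumeration oracle), priors,
and small-scale posterior correctness checks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from csmf import (
    AgeGroup,
    CauseTaxonomy,
    MCMCSettings,
    ModelParameters,
    MultinomialCauseModel,
    linear_predictor,
    log_likelihood,
    log_prior,
    softmax_fractions,
)
from csmf.misclassification import MisclassMatrix, build_matrix

from conftest import make_study


class TestLinearPredictor:
    def test_zero_params_give_zero_eta(self):
        eta = linear_predictor(np.zeros((2, 3)), np.zeros(2), np.ones(3), base_index=0)
        assert np.array_equal(eta, np.zeros(3))

    def test_single_covariate_arithmetic(self):
        # beta row (0, 1) with x = (1, 2): eta = 0*1 + 1*2 = 2
        eta = linear_predictor(np.array([[0.0, 1.0]]), np.zeros(1), np.array([1.0, 2.0]), 0)
        assert eta[0] == 0.0 and eta[1] == 2.0

    def test_random_effect_scales_odds_by_exp(self):
        x = np.array([1.0])
        base = linear_predictor(np.array([[0.3]]), np.zeros(1), x, 0)
        bumped = linear_predictor(np.array([[0.3]]), np.array([0.14]), x, 0)
        p0, p1 = softmax_fractions(base), softmax_fractions(bumped)
        odds_ratio = (p1[1] / p1[0]) / (p0[1] / p0[0])
        assert np.isclose(odds_ratio, np.exp(0.14))

    def test_nonfinite_covariates_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            linear_predictor(np.zeros((1, 2)), np.zeros(1), np.array([1.0, np.inf]), 0)


class TestSoftmax:
    def test_zero_eta_is_uniform(self):
        assert np.allclose(softmax_fractions(np.zeros(4)), 0.25)

    def test_two_cause_closed_form(self):
        p = softmax_fractions(np.array([0.0, np.log(3.0)]))
        assert np.allclose(p, [0.25, 0.75])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-30, 30), min_size=2, max_size=8),
        st.floats(-50, 50),
    )
    def test_shift_invariance_and_normalisation(self, eta, shift):
        eta = np.asarray(eta)
        p1, p2 = softmax_fractions(eta), softmax_fractions(eta + shift)
        assert np.allclose(p1, p2)
        assert np.isclose(p1.sum(), 1.0)

    def test_overflow_safety(self):
        p = softmax_fractions(np.array([1000.0, 0.0]))
        assert np.isfinite(p).all() and np.isclose(p[0], 1.0)


def _params_for(tax, eta_contrasts, n_studies=1):
    """Intercept-only parameters reproducing the given contrast etas."""
    beta = np.array(eta_contrasts, dtype=float)[:, None]
    u = np.zeros((n_studies, len(eta_contrasts)))
    return ModelParameters(beta=beta, u=u, sigma=np.array([0.05]), lam=1.0)


class TestLogLikelihood:
    def test_hand_computed_two_cause_value(self):
        # uniform p, counts (1,1): log[2!/(1!1!) * 0.5^2] = -log 2
        tax = CauseTaxonomy.custom(AgeGroup.CHILD_1TO59M, ("a", "b"), "a")
        study = make_study([1, 1], ("a", "b"))
        m = build_matrix(tax, ("a", "b"), {"a": "a", "b": "b"})
        ll = log_likelihood(_params_for(tax, [0.0]), [study], [m], tax)
        assert np.isclose(ll, -np.log(2.0))

    def test_all_zero_counts_give_zero(self):
        tax = CauseTaxonomy.custom(AgeGroup.CHILD_1TO59M, ("a", "b"), "a")
        study = make_study([0, 0], ("a", "b"))
        m = build_matrix(tax, ("a", "b"), {"a": "a", "b": "b"})
        assert log_likelihood(_params_for(tax, [0.0]), [study], [m], tax) == 0.0

    @pytest.mark.parametrize("C,J", [(2, 2), (3, 2), (3, 3), (4, 2), (4, 3)])
    def test_exhaustive_enumeration_oracle(self, C, J):
        """Aggregated-multinomial likelihood equals the directly computed
        multinomial pmf on merged categories, for every count vector with
        N <= 6."""
        causes = tuple(f"c{i}" for i in range(C))
        tax = CauseTaxonomy.custom(AgeGroup.CHILD_1TO59M, causes, causes[0])
        # deterministic non-uniform p via fixed contrasts
        etas = [0.3 * (i + 1) * (-1) ** i for i in range(C - 1)]
        params = _params_for(tax, etas)
        p = softmax_fractions(np.concatenate([[0.0], etas]))
        # assign causes to J reported categories round-robin (all used)
        assign = [i % J for i in range(C)]
        reported = tuple(f"j{j}" for j in range(J))
        mapping = {causes[i]: reported[assign[i]] for i in range(C)}
        G = build_matrix(tax, reported, mapping)
        q = G.G @ p
        for N in range(0, 7):
            for counts in itertools.product(range(N + 1), repeat=J):
                if sum(counts) != N:
                    continue
                study = make_study(list(counts), reported)
                ll = log_likelihood(params, [study], [G], tax)
                direct = stats.multinomial(N, q).logpmf(counts) if N > 0 else 0.0
                assert np.isclose(ll, direct, atol=1e-10), (counts, q)

    def test_additive_over_studies(self, tiny_taxonomy):
        tax = tiny_taxonomy
        m = build_matrix(tax, tax.causes, {c: c for c in tax.causes})
        s1 = make_study([3, 1, 0, 2], tax.causes, study_id="S1")
        s2 = make_study([0, 5, 1, 1], tax.causes, study_id="S2")
        params = ModelParameters(
            beta=np.array([[0.2], [-0.1], [0.4]]), u=np.zeros((2, 3)),
            sigma=np.array([0.05]), lam=1.0,
        )
        both = log_likelihood(params, [s1, s2], [m, m], tax)
        p1 = ModelParameters(params.beta, np.zeros((1, 3)), params.sigma, 1.0)
        sep = sum(log_likelihood(p1, [s], [m], tax) for s in (s1, s2))
        assert np.isclose(both, sep)


class TestLogPrior:
    def _params(self, slopes, intercept=0.0, sigma=0.05, lam=1.0):
        beta = np.column_stack([[intercept] * len(slopes), slopes])
        return ModelParameters(beta, np.zeros((1, len(slopes))), np.array([sigma]), lam)

    def test_doubling_lambda_doubles_penalty(self):
        slopes = np.array([0.5, -1.2])
        pen1 = log_prior(self._params(slopes, lam=1.0), 0.14) - log_prior(
            self._params(np.zeros(2), lam=1.0), 0.14)
        pen2 = log_prior(self._params(slopes, lam=2.0), 0.14) - log_prior(
            self._params(np.zeros(2), lam=2.0), 0.14)
        assert np.isclose(pen2, 2.0 * pen1)
        assert np.isclose(pen1, -np.abs(slopes).sum())

    def test_intercept_not_penalised(self):
        base = log_prior(self._params(np.zeros(2), intercept=0.0), 0.14)
        moved = log_prior(self._params(np.zeros(2), intercept=3.0), 0.14)
        # the change is exactly the wide-normal term, independent of lambda
        expected = -(3.0**2) / (2 * 10.0**2) * 2
        assert np.isclose(moved - base, expected)

    def test_sigma_above_bound_is_minus_inf(self):
        assert log_prior(self._params(np.zeros(2), sigma=0.15), 0.14) == -np.inf
        assert np.isfinite(log_prior(self._params(np.zeros(2), sigma=0.14), 0.14))


class TestPosterior:
    def test_same_seed_bitwise_identical(self, small_bundle, tax_child, quick_mcmc):
        studies, matrices, _ = small_bundle
        model = MultinomialCauseModel(studies[:6], tax_child, matrices=matrices[:6])
        r1 = model.fit(lam=2.0, settings=quick_mcmc)
        r2 = model.fit(lam=2.0, settings=quick_mcmc)
        assert np.array_equal(r1.draws.beta, r2.draws.beta)
        assert np.array_equal(r1.draws.u, r2.draws.u)
        assert np.array_equal(r1.draws.sigma, r2.draws.sigma)

    def test_two_cause_conjugate_limit(self):
        """Intercept-only 2-cause model with a near-flat logit prior matches
        the analytic Beta(y1, y2) posterior of the binomial fraction."""
        tax = CauseTaxonomy.custom(AgeGroup.CHILD_1TO59M, ("a", "b"), "b")
        study = make_study([30, 70], ("a", "b"))
        model = MultinomialCauseModel([study], tax, sigma_bound=0.005)
        res = model.fit(
            lam=1.0, settings=MCMCSettings(n_chains=2, n_iter=3000, burn_in=1000, seed=5)
        )
        frac_a = res.predict_fractions(np.empty(0))[:, 0]
        beta_post = stats.beta(30, 70)
        assert abs(frac_a.mean() - beta_post.mean()) < 0.015
        assert abs(frac_a.std() - beta_post.std()) < 0.015

    def test_null_data_calibration(self, tax_child, quick_mcmc):
        """Data generated with all covariate effects zero: posterior means of
        non-intercept coefficients stay within 3 posterior SDs of zero."""
        from csmf.simulate import GroundTruth, generate_covariates, generate_studies

        cov = generate_covariates(8, 10, 3, seed=21)
        truth = GroundTruth(beta=np.zeros((7, 4)), sigma=0.0)
        studies, matrices, _ = generate_studies(
            truth, cov, tax_child, [800] * 12, seed=22
        )
        model = MultinomialCauseModel(studies, tax_child, matrices=matrices)
        res = model.fit(lam=1.0, settings=quick_mcmc)
        z = (res.params.values[:, 1:] / res.bse.values[:, 1:])
        assert np.abs(z).max() < 3.0

    def test_fraction_draws_sum_to_one(self, small_bundle, tax_child, quick_mcmc):
        studies, matrices, _ = small_bundle
        model = MultinomialCauseModel(studies[:5], tax_child, matrices=matrices[:5])
        res = model.fit(lam=2.0, settings=quick_mcmc)
        fr = res.fitted_study_fractions()
        assert np.allclose(fr.sum(axis=-1), 1.0)
        pred = res.predict_fractions(np.zeros(3), sample_u=True, seed=1)
        assert np.allclose(pred.sum(axis=-1), 1.0)

    def test_single_chain_rejected(self, small_bundle, tax_child):
        studies, matrices, _ = small_bundle
        model = MultinomialCauseModel(studies[:4], tax_child, matrices=matrices[:4])
        with pytest.raises(ValueError, match="2 chains"):
            model.fit(settings=MCMCSettings(n_chains=1, n_iter=10, burn_in=10))
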