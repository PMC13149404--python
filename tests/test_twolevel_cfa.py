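import numpy as np
import pytest
from scipy import stats

from ildbench import (BASELINE, HYPOTHESIZED, SATURATED, ParamVector,
                      SimCondition, compute_moments, fit_model,
                      implied_covariances, minus2_log_likelihood, model_df,
                      simulate_dataset)
from ildbench.datagen import UnbalancedDataError
from ildbench.twolevel_cfa import ModelSpec, NotPositiveDefiniteError

from conftest import random_psd, random_spd


class TestMoments:
    def test_hand_computed_example(self, toy_dataset):
        m = compute_moments(toy_dataset)
        assert m.s_pw[0, 0] == pytest.approx(2.0)
        assert m.s_b[0, 0] == pytest.approx(16.0)
        assert m.ybar[0] == pytest.approx(3.0)
        assert (m.G, m.c, m.N) == (2, 2, 4)

    def test_cluster_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((12, 3))
        clusters = np.repeat([0, 1, 2], 4)
        m1 = compute_moments(y, clusters)
        m2 = compute_moments(y, np.repeat([7, 5, 9], 4))
        assert np.allclose(m1.s_pw, m2.s_pw)
        assert np.allclose(m1.s_b, m2.s_b)

    def test_zero_within_variation(self):
        y = np.repeat([[1.0], [4.0]], 3, axis=0)
        m = compute_moments(y, [0, 0, 0, 1, 1, 1])
        assert np.allclose(m.s_pw, 0.0)

    def test_unbalanced_rejected(self):
        y = np.arange(5.0)[:, None]
        with pytest.raises(UnbalancedDataError):
            compute_moments(y, [0, 0, 0, 1, 1])

    def test_single_cluster_rejected(self):
        y = np.arange(4.0)[:, None]
        with pytest.raises(UnbalancedDataError):
            compute_moments(y, [0, 0, 0, 0])

    def test_symmetry_and_psd(self, small_sim):
        m = compute_moments(small_sim)
        assert np.allclose(m.s_pw, m.s_pw.T)
        assert np.allclose(m.s_b, m.s_b.T)
        assert np.linalg.eigvalsh(m.s_pw)[0] > -1e-10

    def test_serialization_roundtrip(self, small_sim):
        from ildbench.twolevel_cfa import TwoLevelMoments
        m = compute_moments(small_sim)
        back = TwoLevelMoments.from_dict(m.to_dict())
        assert np.allclose(back.s_pw, m.s_pw)
        assert (back.G, back.c) == (m.G, m.c)


class TestImpliedCovariances:
    def test_zero_loadings_identity(self):
        theta = ParamVector(np.zeros(6), np.ones(6), 1.0,
                            np.zeros(6), np.ones(6), 1.0, np.zeros(6))
        sw, sb, mu = implied_covariances(theta)
        assert np.allclose(sw, np.eye(6))

    def test_direct_product_structure(self):
        lam = np.array([1.0, .7, .7, .7, .7, .7])
        theta = ParamVector(lam, np.full(6, .51), 1.0,
                            lam, np.zeros(6), 1.0, np.zeros(6))
        sw, _, _ = implied_covariances(theta)
        assert sw[1, 2] == pytest.approx(0.49)
        assert sw[0, 1] == pytest.approx(0.7)

    def test_random_params_match_elementwise_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            lw, lb = rng.normal(size=(2, 6))
            tw, tb = rng.uniform(0.1, 2, size=(2, 6))
            pw, pb = rng.uniform(0.1, 2, size=2)
            theta = ParamVector(lw, tw, pw, lb, tb, pb, np.zeros(6))
            sw, sb, _ = implied_covariances(theta)
            assert np.allclose(sw, sw.T) and np.allclose(sb, sb.T)
            j, k = rng.integers(0, 6, 2)
            expect = pw * lw[j] * lw[k] + (tw[j] if j == k else 0.0)
            assert sw[j, k] == pytest.approx(expect)

    def test_pack_unpack_roundtrip(self):
        rng = np.random.default_rng(2)
        lw, lb = rng.normal(size=(2, 6))
        lw[0] = lb[0] = 1.0
        theta = ParamVector(lw, rng.uniform(.1, 2, 6), 1.3,
                            lb, rng.uniform(.1, 2, 6), 0.4, rng.normal(size=6))
        back = ParamVector.unpack(theta.pack(0), theta.mu, 0)
        for name in ("lambda_w", "theta_w", "lambda_b", "theta_b", "mu"):
            assert np.allclose(getattr(back, name), getattr(theta, name))
        assert back.phi_w == theta.phi_w and back.phi_b == theta.phi_b


def _dense_minus2ll(y, clusters, sigma_w, sigma_b, mu):
    """Oracle: stacked multivariate normal with I_c (x) Sw + J_c (x) Sb."""
    total = 0.0
    for g in np.unique(clusters):
        block = y[clusters == g]
        c, p = block.shape
        omega = np.kron(np.eye(c), sigma_w) + np.kron(np.ones((c, c)), sigma_b)
        mean = np.tile(mu, c)
        total += -2.0 * stats.multivariate_normal.logpdf(
            block.ravel(), mean=mean, cov=omega)
    return total


class TestLikelihood:
    def test_all_zero_closed_form(self):
        y = np.zeros((6, 2))
        m = compute_moments(y, [0, 0, 1, 1, 2, 2])
        ll = minus2_log_likelihood(m, np.eye(2), np.zeros((2, 2)), np.zeros(2))
        assert ll == pytest.approx(12 * np.log(2 * np.pi))

    def test_matches_dense_gaussian_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(100):
            G = int(rng.integers(2, 6))
            c = int(rng.integers(2, 5))
            p = int(rng.integers(1, 4))
            y = rng.standard_normal((G * c, p))
            clusters = np.repeat(np.arange(G), c)
            m = compute_moments(y, clusters)
            sw = random_spd(rng, p)
            sb = random_psd(rng, p)
            mu = rng.standard_normal(p)
            ours = minus2_log_likelihood(m, sw, sb, mu)
            oracle = _dense_minus2ll(y, clusters, sw, sb, mu)
            assert ours == pytest.approx(oracle, abs=1e-8 * max(1, abs(oracle)))

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal((12, 3))
        clusters = np.repeat([0, 1, 2], 4)
        sw, sb = random_spd(rng, 3), random_psd(rng, 3)
        mu = rng.standard_normal(3)
        shift = rng.standard_normal(3)
        a = minus2_log_likelihood(compute_moments(y, clusters), sw, sb, mu)
        b = minus2_log_likelihood(compute_moments(y + shift, clusters),
                                  sw, sb, mu + shift)
        assert a == pytest.approx(b, abs=1e-8)

    def test_non_pd_rejected(self):
        y = np.random.default_rng(5).standard_normal((8, 2))
        m = compute_moments(y, [0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(NotPositiveDefiniteError):
            minus2_log_likelihood(m, -np.eye(2), np.zeros((2, 2)), np.zeros(2))


class TestModelDf:
    def test_counting(self):
        assert model_df(HYPOTHESIZED) == 18
        assert model_df(SATURATED) == 0
        assert model_df(BASELINE) == 30

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("exploratory")


class TestFitting:
    def test_saturated_is_constrained_optimum(self, small_sim):
        # the closed-form PSD-constrained fit must not be improvable by any
        # feasible perturbation of (Sigma_w, Sigma_b)
        m = compute_moments(small_sim)
        fit = fit_model(m, SATURATED)
        rng = np.random.default_rng(6)
        for _ in range(50):
            dw = rng.standard_normal((m.p, m.p)) * 0.05
            db = rng.standard_normal((m.p, m.p)) * 0.05
            sw = fit.sigma_w + (dw + dw.T) / 2
            ev, vec = np.linalg.eigh(fit.sigma_b + (db + db.T) / 2)
            sb = vec @ np.diag(np.maximum(ev, 0.0)) @ vec.T
            try:
                ll = minus2_log_likelihood(m, sw, sb, m.ybar)
            except NotPositiveDefiniteError:
                continue
            assert ll >= fit.minus2ll - 1e-8

    def test_saturated_unconstrained_when_between_definite(self):
        # strong between structure: no truncation, textbook closed form
        cond = SimCondition(100, 10, 3.0, seed=8)
        m = compute_moments(simulate_dataset(cond))
        fit = fit_model(m, SATURATED)
        if not fit.between_indefinite:
            expect = (m.N * m.p * np.log(2 * np.pi)
                      + (m.N - m.G) * (np.linalg.slogdet(m.s_pw)[1] + m.p)
                      + m.G * (np.linalg.slogdet(
                          (m.G - 1) / m.G * m.s_b)[1] + m.p))
            assert fit.minus2ll == pytest.approx(expect, abs=1e-6)

    def test_noise_free_parameter_recovery(self):
        # build moments directly from a known parameter vector
        lam = np.array([1.0, 1.1, 0.9, 1.0, 1.2, 0.8])
        truth = ParamVector(lam, np.full(6, 0.5), 0.9,
                            lam, np.full(6, 0.2), 0.4, np.zeros(6))
        sw, sb, mu = implied_covariances(truth)
        from ildbench.twolevel_cfa import TwoLevelMoments
        G, c = 200, 10
        m = TwoLevelMoments(sw, sw + c * sb, mu, G, c)
        fit = fit_model(m, HYPOTHESIZED)
        assert fit.converged
        assert np.allclose(fit.params.lambda_w, truth.lambda_w, atol=1e-4)
        assert np.allclose(fit.params.theta_w, truth.theta_w, atol=1e-4)
        assert np.allclose(fit.params.lambda_b, truth.lambda_b, atol=1e-3)
        assert fit.params.phi_w == pytest.approx(0.9, abs=1e-4)

    def test_likelihood_ordering(self, small_sim):
        m = compute_moments(small_sim)
        ll = {kind: fit_model(m, spec).minus2ll
              for kind, spec in [("sat", SATURATED), ("hyp", HYPOTHESIZED),
                                 ("base", BASELINE)]}
        assert ll["sat"] <= ll["hyp"] + 1e-6
        assert ll["hyp"] <= ll["base"] + 1e-6

    def test_chi2_scale_equivariance(self, small_sim):
        df = small_sim.df.copy()
        df["item3"] = df["item3"] * 7.5
        scaled = type(small_sim)(df, None)

        def chi2(data):
            m = compute_moments(data)
            return (fit_model(m, HYPOTHESIZED).minus2ll
                    - fit_model(m, SATURATED).minus2ll)
        assert chi2(small_sim) == pytest.approx(chi2(scaled), abs=1e-6)

    def test_nonconvergence_is_flagged_not_raised(self, small_sim):
        # a fit starting from an absurd point must still return a FitResult
        m = compute_moments(small_sim)
        bad = ParamVector(np.full(6, 50.0), np.full(6, 1e-8), 1e-8,
                          np.full(6, -50.0), np.zeros(6), 0.0, m.ybar)
        bad = ParamVector(bad.lambda_w, bad.theta_w, bad.phi_w,
                          bad.lambda_b, bad.theta_b, bad.phi_b, m.ybar)
        fit = fit_model(m, HYPOTHESIZED, start=bad)
        assert isinstance(fit.converged, bool)
        assert np.isfinite(fit.minus2ll)
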