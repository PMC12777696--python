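"""GGM parameterization, stationary covariance, implied moments, deviance."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from panelgvar.params import (
    GGM,
    NotPositiveDefiniteError,
    PanelGVARParams,
    ParamMasks,
    StationarityError,
    ggm_precision,
    implied_moments,
    neg2_loglik,
    partial_correlations,
    stationary_within_cov,
)


def random_stable_params(p, rng, t_scale=0.3, omega_scale=0.2):
    beta = rng.uniform(-t_scale, t_scale, size=(p, p))
    ev = np.max(np.abs(np.linalg.eigvals(beta)))
    if ev > 0.8:
        beta *= 0.8 / ev
    def rand_ggm():
        m = rng.uniform(-omega_scale, omega_scale, size=(p, p))
        omega = np.triu(m, 1) + np.triu(m, 1).T
        while np.min(np.linalg.eigvalsh(np.eye(p) - omega)) < 0.05:
            omega *= 0.9
        return GGM(omega, rng.uniform(0.8, 1.5, size=p))
    return PanelGVARParams(mu=rng.normal(size=p), beta=beta, contemporaneous=rand_ggm(), between=rand_ggm())


class TestGGM:
    def test_empty_network_gives_identity_precision(self):
        g = GGM(np.zeros((3, 3)), np.ones(3))
        np.testing.assert_allclose(ggm_precision(g), np.eye(3))

    def test_two_node_closed_form(self):
        g = GGM(np.array([[0, 0.5], [0.5, 0]]), np.ones(2))
        np.testing.assert_allclose(ggm_precision(g), [[1, -0.5], [-0.5, 1]])
        cov = g.covariance()
        corr = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert corr == pytest.approx(0.5)

    def test_partial_correlation_inversion_identity(self):
        rng = np.random.default_rng(4)
        g = random_stable_params(4, rng).contemporaneous
        k = ggm_precision(g)
        np.testing.assert_allclose(partial_correlations(k), g.omega, atol=1e-12)

    def test_roundtrip_from_covariance(self):
        rng = np.random.default_rng(5)
        g = random_stable_params(5, rng).between
        g2 = GGM.from_covariance(g.covariance())
        np.testing.assert_allclose(g2.omega, g.omega, atol=1e-10)
        np.testing.assert_allclose(g2.delta, g.delta, atol=1e-10)

    def test_non_pd_omega_rejected(self):
        omega = np.array([[0, 0.9, 0.9], [0.9, 0, 0.9], [0.9, 0.9, 0]])
        with pytest.raises(NotPositiveDefiniteError):
            ggm_precision(GGM(omega, np.ones(3)))


class TestStationaryCov:
    def test_zero_temporal_returns_innovation_cov(self):
        sz = np.array([[2.0, 0.3], [0.3, 1.0]])
        np.testing.assert_allclose(stationary_within_cov(np.zeros((2, 2)), sz), sz)

    def test_scalar_closed_form(self):
        out = stationary_within_cov(np.array([[0.5]]), np.array([[1.0]]))
        assert out[0, 0] == pytest.approx(4 / 3)

    @pytest.mark.parametrize("seed", range(20))
    def test_fixed_point_iteration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pr = random_stable_params(5, rng)
        sz = pr.contemporaneous.covariance()
        sol = stationary_within_cov(pr.beta, sz)
        it = np.zeros_like(sz)
        for _ in range(10000):
            nxt = pr.beta @ it @ pr.beta.T + sz
            if np.max(np.abs(nxt - it)) < 1e-14:
                it = nxt
                break
            it = nxt
        assert np.max(np.abs(sol - it)) < 1e-10

    def test_explosive_matrix_rejected(self):
        with pytest.raises(StationarityError):
            stationary_within_cov(np.array([[1.1]]), np.array([[1.0]]))


class TestImpliedMoments:
    def test_no_dynamics_no_between_is_block_diagonal(self):
        p = 3
        pr = PanelGVARParams(
            mu=np.zeros(p),
            beta=np.zeros((p, p)),
            contemporaneous=GGM(np.zeros((p, p)), np.ones(p)),
            between=GGM(np.zeros((p, p)), np.full(p, 1e4)),  # negligible between variance
        )
        _, cov = implied_moments(pr, T=3)
        off = cov[:p, p : 2 * p]
        np.testing.assert_allclose(off, 0, atol=1e-7)
        np.testing.assert_allclose(cov[:p, :p], cov[p : 2 * p, p : 2 * p] + 0, atol=1e-12)

    def test_random_intercept_only_blocks_equal_sigma_b(self):
        rng = np.random.default_rng(7)
        pr = random_stable_params(3, rng)
        pr.beta = np.zeros((3, 3))
        sigma_b = pr.between.covariance()
        _, cov = implied_moments(pr, T=4)
        for t in range(4):
            for s in range(t):
                np.testing.assert_allclose(cov[t * 3 : (t + 1) * 3, s * 3 : (s + 1) * 3], sigma_b, atol=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_implied_cov_symmetric_pd_on_random_draws(self, seed):
        rng = np.random.default_rng(1000 + seed)
        pr = random_stable_params(4, rng)
        _, cov = implied_moments(pr, T=4)
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.min(np.linalg.eigvalsh(cov)) > 0

    def test_mean_is_mu_tiled(self):
        rng = np.random.default_rng(9)
        pr = random_stable_params(3, rng)
        mean, _ = implied_moments(pr, T=4)
        np.testing.assert_array_equal(mean, np.tile(pr.mu, 4))


class TestDeviance:
    def _sample_moments(self, x):
        m = x.mean(axis=0)
        c = (x - m).T @ (x - m) / len(x)
        return m, c

    def test_equals_sum_of_mvn_log_densities(self):
        rng = np.random.default_rng(11)
        pr = random_stable_params(3, rng)
        mean, cov = implied_moments(pr, T=3)
        x = rng.multivariate_normal(mean, cov, size=20)
        sm, sc = self._sample_moments(x)
        dev = neg2_loglik(pr, sm, sc, 20, T=3)
        oracle = -2 * multivariate_normal(mean, cov).logpdf(x).sum()
        assert dev == pytest.approx(oracle, abs=1e-8)

    def test_translation_invariance(self):
        rng = np.random.default_rng(12)
        pr = random_stable_params(2, rng)
        mean, cov = implied_moments(pr, T=3)
        x = rng.multivariate_normal(mean, cov, size=30)
        sm, sc = self._sample_moments(x)
        d0 = neg2_loglik(pr, sm, sc, 30, T=3)
        pr2 = pr.copy()
        pr2.mu = pr.mu + 5.0
        d1 = neg2_loglik(pr2, sm + np.tile(5.0, len(sm)), sc, 30, T=3)
        assert d1 == pytest.approx(d0, rel=1e-12)

    def test_saturated_discrepancy_is_zero(self):
        """log|S| + tr(S S^-1) - log|S| - pT = 0 at the saturated optimum."""
        rng = np.random.default_rng(13)
        a = rng.normal(size=(40, 6))
        s = (a - a.mean(0)).T @ (a - a.mean(0)) / 40
        val = np.linalg.slogdet(s)[1] + np.trace(s @ np.linalg.inv(s)) - np.linalg.slogdet(s)[1] - 6
        assert val == pytest.approx(0.0, abs=1e-10)


class TestMaskInvariants:
    def test_fixed_nonzero_entries_rejected(self):
        rng = np.random.default_rng(14)
        pr = random_stable_params(3, rng)
        masks = ParamMasks.saturated(3)
        masks.beta[0, 1] = False
        pr.masks = masks
        assert pr.beta[0, 1] != 0
        with pytest.raises(ValueError, match="fixed"):
            pr.validate()

    def test_with_masks_zeroes_fixed_entries(self):
        rng = np.random.default_rng(15)
        pr = random_stable_params(3, rng)
        masks = ParamMasks.saturated(3)
        masks.beta[0, 1] = False
        masks.omega_zeta[0, 2] = masks.omega_zeta[2, 0] = False
        pr2 = pr.with_masks(masks)
        assert pr2.beta[0, 1] == 0 and pr2.contemporaneous.omega[0, 2] == 0
        pr2.validate()

    def test_free_parameter_count(self):
        p = 4
        masks = ParamMasks.saturated(p)
        rng = np.random.default_rng(16)
        pr = random_stable_params(p, rng)
        pr.masks = masks
        # mu(4) + delta_z(4) + delta_b(4) + beta(16) + omega_z(6) + omega_b(6)
        assert pr.n_free == 40
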