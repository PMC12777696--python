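"""ML fitting: recovery of null models, optimality, stability, Wald calibration."""

import numpy as np
import pytest

from panelgvar.model import FitOptions, PanelGVAR
from panelgvar.params import GGM, PanelGVARParams, ParamMasks
from panelgvar.synthetic import GroundTruth, simulate_panel

from conftest import single_edge_truth


def null_truth(p=3, n=2000, seed=0):
    params = PanelGVARParams(
        mu=np.zeros(p),
        beta=np.zeros((p, p)),
        contemporaneous=GGM(np.zeros((p, p)), np.ones(p)),
        between=GGM(np.zeros((p, p)), np.full(p, 1.2)),
    )
    return GroundTruth(params=params, thresholds=None, reverse_items=frozenset(), n_subjects=n, n_waves=4, seed=seed)


@pytest.fixture(scope="module")
def null_fit():
    truth = null_truth(seed=21)
    sim = simulate_panel(truth)
    model = PanelGVAR(sim.latent, 3, 4)
    return truth, model, model.fit()


class TestFitNullModel:
    def test_converges(self, null_fit):
        _, _, fit = null_fit
        assert fit.converged

    def test_off_diagonal_estimates_within_3se_of_zero(self, null_fit):
        _, _, fit = null_fit
        assert fit.se_available
        se = fit.se
        p = 3
        off = ~np.eye(p, dtype=bool)
        assert np.all(np.abs(fit.params.beta[off]) <= 3 * se.beta[off])
        iu = np.triu_indices(p, 1)
        assert np.all(np.abs(fit.params.contemporaneous.omega[iu]) <= 3 * se.contemporaneous.omega[iu])
        assert np.all(np.abs(fit.params.between.omega[iu]) <= 3 * se.between.omega[iu])

    def test_deviance_at_truth_bounds_mle_deviance(self, null_fit):
        truth, model, fit = null_fit
        assert model.deviance(truth.params) >= fit.deviance - 1e-6

    def test_bic_identity(self, null_fit):
        _, _, fit = null_fit
        assert fit.bic == pytest.approx(fit.n_free * np.log(fit.nobs) - 2 * fit.llf, rel=1e-12)


class TestOptimizerBehaviour:
    def test_multistart_deviance_spread_small(self):
        truth = single_edge_truth(p=3, omega_edge=(0, 1), n_subjects=500, seed=33)
        sim = simulate_panel(truth)
        model = PanelGVAR(sim.latent, 3, 4)
        base = model.fit()
        rng = np.random.default_rng(5)
        devs = [base.deviance]
        for _ in range(4):
            start = base.params.copy()
            start.mu = start.mu + rng.normal(scale=0.05, size=3)
            start.beta = start.beta + rng.normal(scale=0.05, size=(3, 3))
            devs.append(model.fit(start=start).deviance)
        assert max(devs) - min(devs) < 1e-4

    def test_fit_deterministic_given_seed(self):
        truth = single_edge_truth(p=3, n_subjects=300, seed=8)
        sim = simulate_panel(truth)
        model = PanelGVAR(sim.latent, 3, 4)
        opts = FitOptions(n_restarts=2, seed=99)
        f1 = model.fit(options=opts)
        f2 = model.fit(options=opts)
        assert f1.deviance == f2.deviance
        np.testing.assert_array_equal(f1.params.beta, f2.params.beta)

    def test_nested_model_never_beats_full_likelihood(self):
        truth = single_edge_truth(p=3, n_subjects=400, seed=12)
        sim = simulate_panel(truth)
        model = PanelGVAR(sim.latent, 3, 4)
        full = model.fit()
        masks = ParamMasks.saturated(3)
        masks.beta[0, 1] = masks.beta[1, 0] = False
        masks.omega_zeta[0, 1] = masks.omega_zeta[1, 0] = False
        nested = model.fit(masks=masks)
        assert nested.llf <= full.llf + 1e-6

    def test_packer_roundtrip(self):
        from panelgvar.model import _Packer

        rng = np.random.default_rng(3)
        truth = single_edge_truth(p=4, seed=1)
        masks = ParamMasks.saturated(4)
        masks.beta[2, 1] = False
        pr = truth.params.with_masks(masks)
        pr.beta[0, 1] = 0.15
        packer = _Packer(4, masks, log_delta=True)
        back = packer.unpack(packer.pack(pr))
        np.testing.assert_allclose(back.beta, pr.beta, atol=1e-14)
        np.testing.assert_allclose(back.contemporaneous.omega, pr.contemporaneous.omega, atol=1e-14)
        np.testing.assert_allclose(back.contemporaneous.delta, pr.contemporaneous.delta, atol=1e-12)

    def test_incomplete_data_rejected(self):
        x = np.full((10, 12), np.nan)
        with pytest.raises(ValueError, match="missing"):
            PanelGVAR(x, 3, 4)


class TestWaldCalibration:
    def test_z_for_true_zero_edges_standard_normal(self):
        """Pooled Wald z over truly-zero edges: near-zero mean, unit-ish SD."""
        zs = []
        p = 3
        off = ~np.eye(p, dtype=bool)
        iu = np.triu_indices(p, 1)
        for rep in range(30):
            truth = null_truth(p=p, n=1000, seed=500 + rep)
            sim = simulate_panel(truth)
            fit = PanelGVAR(sim.latent, p, 4).fit()
            if not (fit.converged and fit.se_available):
                continue
            se = fit.se
            zs.extend((fit.params.beta[off] / se.beta[off]).tolist())
            zs.extend((fit.params.contemporaneous.omega[iu] / se.contemporaneous.omega[iu]).tolist())
            zs.extend((fit.params.between.omega[iu] / se.between.omega[iu]).tolist())
        zs = np.array(zs)
        assert len(zs) >= 300
        assert abs(zs.mean()) < 0.15
        assert 0.8 <= zs.std() <= 1.2


class TestResultsSurface:
    def test_edge_table_and_summary(self, single_edge_fit):
        truth, model, fit = single_edge_fit
        tab = fit.edge_table()
        assert set(tab.network) == {"temporal", "contemporaneous", "between"}
        strongest = tab[tab.network == "contemporaneous"].sort_values("weight", key=abs).iloc[-1]
        assert {strongest["from"], strongest["to"]} == {"y1", "y2"}
        assert strongest.weight == pytest.approx(0.4, abs=0.08)
        text = fit.summary()
        assert "BIC" in text and "temporal network" in text

    def test_implied_moments_close_to_sample(self, single_edge_fit):
        _, model, fit = single_edge_fit
        _, cov = fit.implied_moments()
        assert np.max(np.abs(cov - model.sample_cov)) < 0.2

    def test_networkx_export_weights(self, single_edge_fit):
        _, _, fit = single_edge_fit
        g = fit.to_networkx("contemporaneous")
        w = g.get_edge_data("y1", "y2")["weight"]
        assert w == pytest.approx(fit.params.contemporaneous.omega[0, 1])
        dg = fit.to_networkx("temporal")
        assert dg.is_directed()
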