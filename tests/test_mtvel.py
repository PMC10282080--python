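"""MT velocity GLM: optimizer contracts, preferred direction, temporal
projection and von Mises tuning."""
import numpy as np
import pytest
import scipy.sparse as sp

from fvrf.gazestim import Grid, VelocityStimulus, decompose_velocity
from fvrf.mtvel import (
    DirectionTuning,
    VelocityGLM,
    VelocityGLMResults,
    direction_tuning_forward,
    fit_von_mises,
)
from fvrf.simulate import (
    NeuronModel,
    gen_eye_trace,
    gen_motion_dot_stimulus,
    simulate_neuron,
)


@pytest.fixture(scope="module")
def mt_session():
    trace, _ = gen_eye_trace(61.0, seed=1, bounds_frac=0.3)
    motion = gen_motion_dot_stimulus(6000, seed=2)
    grid = Grid.centered((20.0, 12.0), 2.0)
    vstim = decompose_velocity(motion, trace, grid)
    return trace, motion, grid, vstim


class TestVelocityGLM:
    def test_null_unit_recovers_intercept_mle(self, mt_session):
        _, _, _, vstim = mt_session
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.1, size=6000).astype(float)
        res = VelocityGLM(vstim, counts, n_lags=5).fit()
        target = np.log(counts.mean())
        assert abs(res.bias / target - 1) < 0.05
        assert np.abs(res.weights).max() < 0.01

    def test_infinite_l1_zeroes_all_weights(self, mt_session):
        _, _, _, vstim = mt_session
        rng = np.random.default_rng(1)
        counts = rng.poisson(0.1, size=6000).astype(float)
        res = VelocityGLM(vstim, counts, n_lags=3).fit(
            lambda_grid=(1.0,), gamma_grid=(1e9,)
        )
        assert np.all(res.weights == 0.0)

    def test_objective_monotone_and_stationary(self, mt_session):
        trace, motion, _, vstim = mt_session
        m = NeuronModel(kind="mt", center=(2.0, 0.0), pref_dir=0.5,
                        dir_kappa=3.0, envelope_sigma=2.0, baseline=4.0,
                        gain=10.0)
        _, counts, _ = simulate_neuron(m, motion, trace, seed=3)
        res = VelocityGLM(vstim, counts, n_lags=4).fit(
            lambda_grid=(10.0,), gamma_grid=(0.0,), max_iter=800, tol=1e-9
        )
        obj = res.objective_trace
        assert np.all(np.diff(obj) <= 1e-8 * np.abs(obj[:-1]) + 1e-9)
        # at gamma=0 the solution must satisfy smooth stationarity
        assert res.final_grad_norm < 1e-6 * max(1.0, abs(obj[-1]))


class TestPreferredDirection:
    def _results(self, weights):
        return VelocityGLMResults(
            model=None, weights=weights, bias=0.0, lambda_=1.0, gamma=0.0,
            converged=True, final_grad_norm=0.0,
            objective_trace=np.array([0.0]), heldout_nll=0.0,
        )

    def test_single_cell_vertical_vector(self):
        w = np.zeros((2, 5, 2))
        w[1, 3] = [0.0, 3.0]
        res = self._results(w)
        vec, peak = res.preferred_direction()
        assert peak == 3
        assert np.isclose(res.preferred_direction_deg(), 90.0)

    def test_cancellation_raises(self):
        w = np.zeros((1, 4, 2))
        w[0, 0] = [1.0, 0.0]
        w[0, 1] = [-1.0, 0.0]
        with pytest.raises(ValueError):
            self._results(w).preferred_direction()

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            self._results(np.zeros((2, 4, 2))).preferred_direction()

    def test_temporal_projection_definition(self):
        w = np.zeros((3, 4, 2))
        w[:, 2] = [[1.0, 1.0], [2.0, 2.0], [0.5, 0.5]]
        res = self._results(w)
        proj = res.temporal_projection()
        # projection at the peak cell = amplitude * cos(angle to preferred)=|v|
        amps = np.linalg.norm(w[:, 2], axis=1)
        assert np.allclose(proj["in_rf"], amps)
        assert np.allclose(proj["out_rf"], 0.0)

    def test_flat_field_flat_profile(self):
        w = np.tile(np.array([1.0, 0.0]), (3, 4, 1))
        proj = self._results(w).temporal_projection()
        assert np.allclose(proj["in_rf"], proj["in_rf"][0])


class TestDirectionTuning:
    def test_tuned_unit_peaks_at_true_direction(self, mt_session):
        trace, motion, grid, vstim = mt_session
        pref = np.radians(90.0)
        m = NeuronModel(kind="mt", center=(2.0, 0.0), pref_dir=pref,
                        dir_kappa=3.0, envelope_sigma=2.0, baseline=2.0,
                        gain=15.0)
        _, counts, _ = simulate_neuron(m, motion, trace, seed=5)
        xx, yy = grid.cell_centers()
        mask = np.hypot(xx - 2.0, yy) <= 3.0
        tun = direction_tuning_forward(motion, counts, trace, mask, grid,
                                       peak_lag=2, seed=0)
        peak_dir = np.degrees(tun.directions[tun.preferred_index])
        err = abs((peak_dir - 90.0 + 180) % 360 - 180)
        assert err <= 22.5  # within one direction bin
        assert np.all(tun.ci_low <= tun.rates + 1e-9)
        assert np.all(tun.rates <= tun.ci_high + 1e-9)

    def test_untuned_unit_rates_overlap_cis(self, mt_session):
        trace, motion, grid, _ = mt_session
        rng = np.random.default_rng(7)
        counts = rng.poisson(0.15, size=6000).astype(float)
        mask = np.ones(grid.n_cells, dtype=bool)
        tun = direction_tuning_forward(motion, counts, trace, mask, grid,
                                       peak_lag=2, seed=0)
        # every rate lies within every other direction's 95% CI band
        assert np.all(tun.rates <= tun.ci_high.max() + 1e-9)
        assert np.all(tun.rates >= tun.ci_low.min() - 1e-9)


class TestVonMises:
    def test_value_at_preferred_and_flat_limit(self):
        from fvrf.mtvel import VonMisesFit

        f = VonMisesFit(b=2.0, A=5.0, K=3.0, theta_hat=1.0, r2=1.0)
        assert np.isclose(f(1.0), 7.0)  # b + A at theta_hat
        f0 = VonMisesFit(b=2.0, A=5.0, K=0.0, theta_hat=1.0, r2=1.0)
        th = np.linspace(0, 2 * np.pi, 16)
        assert np.allclose(f0(th), 7.0)  # K=0: constant b + A

    def test_noiseless_recovery(self):
        th = np.arange(16) * 2 * np.pi / 16
        true = dict(b=3.0, A=12.0, K=2.2, theta_hat=np.radians(110.0))
        rates = true["b"] + true["A"] * np.exp(
            true["K"] * (np.cos(th - true["theta_hat"]) - 1)
        )
        fit = fit_von_mises((th, rates))
        assert abs(fit.b - true["b"]) < 1e-6
        assert abs(fit.A - true["A"]) < 1e-6
        assert abs(fit.K - true["K"]) < 1e-6
        assert abs(fit.theta_hat - true["theta_hat"]) < 1e-6
        assert fit.r2 > 1 - 1e-12

    def test_flat_data_flagged(self):
        th = np.arange(16) * 2 * np.pi / 16
        fit = fit_von_mises((th, np.full(16, 5.0)))
        assert fit.flagged

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_von_mises((np.arange(4.0), np.arange(4.0)))
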