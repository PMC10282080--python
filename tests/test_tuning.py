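"""Polar basis, parametric tuning surface and forward correlation."""
import numpy as np
import pytest
from scipy.optimize import brentq

from fvrf.simulate import NeuronModel, gen_eye_trace, gen_grating_stimulus, simulate_neuron
from fvrf.tuning import (
    GratingTuningModel,
    PolarBasis,
    evaluate_tuning_model,
    fit_tuning_model,
    forward_correlation_temporal,
    orientation_bandwidth,
    project_polar_basis,
    sf_bandwidth,
)


class TestPolarBasis:
    def test_blank_frames_map_to_zero(self):
        g = gen_grating_stimulus(200, blank_prob=0.5, seed=0)
        X = project_polar_basis(g, PolarBasis())
        assert np.all(X[g.blank] == 0)
        assert np.any(X[~g.blank] != 0)

    def test_basis_node_peaks_at_one(self):
        b = PolarBasis()
        for i_ori in (0, 3):
            for i_sf in (0, 2):
                theta = b.ori_centers[i_ori]
                omega = np.expm1(b.sf_centers_log[i_sf])
                row = b.evaluate(np.array([theta]), np.array([omega]))[0]
                assert np.isclose(row[i_sf * b.n_ori + i_ori], 1.0)

    def test_rows_match_independent_evaluation(self):
        b = PolarBasis()
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, np.pi, 50)
        omega = rng.uniform(1, 16, 50)
        rows = b.evaluate(theta, omega)
        # independent re-implementation of the basis formulas
        for n in range(50):
            for i_sf in range(4):
                for i_ori in range(8):
                    o = np.exp(b.kappa_b * (np.cos(2 * (theta[n] - i_ori * np.pi / 8)) - 1))
                    u = np.log1p(omega[n]) - b.sf_centers_log[i_sf]
                    s = 0.5 * (1 + np.cos(np.pi * u / b.sf_delta)) if abs(u) <= b.sf_delta else 0.0
                    assert np.isclose(rows[n, i_sf * 8 + i_ori], o * s, atol=1e-12)


class TestTuningSurface:
    P = dict(b=3.0, M=40.0, kappa=2.5, sigma=0.35, theta_hat=1.1, omega_hat=4.0)

    def test_peak_and_trough_values(self):
        p = self.P
        at_peak = evaluate_tuning_model(**p, theta=p["theta_hat"],
                                        omega=p["omega_hat"])
        assert np.isclose(at_peak, p["M"])
        ortho = evaluate_tuning_model(**p, theta=p["theta_hat"] + np.pi / 2,
                                      omega=p["omega_hat"])
        assert np.isclose(ortho, p["b"])

    def test_pi_periodic_orientation(self):
        p = self.P
        th = np.linspace(0, np.pi, 17)
        a = evaluate_tuning_model(**p, theta=th, omega=2.0)
        c = evaluate_tuning_model(**p, theta=th + np.pi, omega=2.0)
        assert np.allclose(a, c, atol=1e-12)

    def test_range_bounded_by_baseline_and_max(self):
        p = self.P
        th, om = np.meshgrid(np.linspace(0, np.pi, 40), np.geomspace(0.5, 20, 30))
        vals = evaluate_tuning_model(**p, theta=th, omega=om)
        assert vals.min() >= p["b"] - 1e-9
        assert vals.max() <= p["M"] + 1e-9

    def test_bandwidths_against_numeric_root(self):
        for kappa in (0.05, 0.5, 2.0, 8.0):
            O = lambda d: (np.exp(kappa * np.cos(d) ** 2) - 1) / (np.exp(kappa) - 1)
            half = brentq(lambda d: O(d) - 0.5, 1e-9, np.pi / 2 - 1e-9)
            assert np.isclose(orientation_bandwidth(kappa), 2 * half, rtol=1e-8)
        # kappa -> 0 limit: full width at half height tends to pi/2
        assert abs(orientation_bandwidth(1e-6) - np.pi / 2) < 1e-3
        # sf bandwidth from the log-gaussian half-height points
        s, om = 0.35, 4.0
        S = lambda w: np.exp(-((np.log1p(w) - np.log1p(om)) ** 2) / (2 * s**2))
        lo = brentq(lambda w: S(w) - 0.5, 1e-6, om)
        hi = brentq(lambda w: S(w) - 0.5, om, 1e3)
        assert np.isclose(sf_bandwidth(s, om), hi - lo, rtol=1e-8)

    def test_noiseless_parameter_recovery_within_one_percent(self):
        p = self.P
        theta = np.arange(36) * np.pi / 36
        omega = np.geomspace(1, 16, 24)
        tt, ww = np.meshgrid(theta, omega, indexing="ij")
        z = evaluate_tuning_model(**p, theta=tt, omega=ww)
        fit = fit_tuning_model(z, theta, omega)
        assert abs(fit.b / p["b"] - 1) < 0.01
        assert abs(fit.M / p["M"] - 1) < 0.01
        assert abs(fit.kappa / p["kappa"] - 1) < 0.01
        assert abs(fit.sigma / p["sigma"] - 1) < 0.01
        assert abs(fit.theta_hat / p["theta_hat"] - 1) < 0.01
        assert abs(fit.omega_hat / p["omega_hat"] - 1) < 0.01


class TestSubspaceReverseCorrelation:
    def test_tuned_unit_peaks_at_its_node(self):
        b = PolarBasis()
        seeds = np.random.SeedSequence(5).generate_state(3) % 2**31
        trace, _ = gen_eye_trace(101.0, seed=int(seeds[0]))
        g = gen_grating_stimulus(6000, seed=int(seeds[1]))
        pref_ori = b.ori_centers[3]
        pref_sf = float(np.expm1(b.sf_centers_log[1]))
        m = NeuronModel(kind="tuned", pref_ori=pref_ori, pref_sf=pref_sf,
                        kappa=3.0, sf_sigma=0.3, baseline=2.0, max_rate=50.0)
        _, counts, _ = simulate_neuron(m, g, trace, seed=int(seeds[2]))
        gm = GratingTuningModel(g, counts, basis=b, n_lags=6)
        res = gm.fit()
        k = res.params[:, 0].reshape(6, -1)[res.peak_lag(0)]
        assert np.argmax(k) == 1 * 8 + 3  # the unit's own basis node
        tf = gm.tuning(res)
        err = abs(np.angle(np.exp(2j * (tf.theta_hat - pref_ori)))) / 2
        assert np.degrees(err) < 5

    def test_null_unit_coefficients_shrink(self):
        rng = np.random.default_rng(0)
        g = gen_grating_stimulus(4000, seed=1)
        counts = rng.poisson(0.2, size=4000).astype(float)
        gm = GratingTuningModel(g, counts, n_lags=4)
        res = gm.fit()
        # heavily regularized: coefficients near zero relative to rate scale
        assert np.abs(res.params).max() < 0.05


class TestForwardCorrelation:
    def _fit(self):
        from fvrf.tuning import TuningFit

        return TuningFit(b=2.0, M=40.0, kappa=2.5, sigma=0.35, theta_hat=1.0,
                         omega_hat=4.0, ori_bandwidth=1.0, sf_bandwidth=4.0,
                         r2=1.0)

    def test_stimulus_independent_unit_flat(self):
        rng = np.random.default_rng(3)
        g = gen_grating_stimulus(20000, seed=2)
        rate = 10.0
        counts = rng.poisson(rate / 60.0, size=20000).astype(float)
        out = forward_correlation_temporal(g, counts, self._fit(), n_lags=10)
        se = rate / np.sqrt(out["n_preferred_onsets"] / 60.0)
        assert np.nanmax(np.abs(out["preferred"] - rate)) < 3 * max(se, 1.0)

    def test_peak_lag_matches_temporal_kernel(self):
        seeds = np.random.SeedSequence(9).generate_state(3) % 2**31
        trace, _ = gen_eye_trace(168.0, seed=int(seeds[0]))
        g = gen_grating_stimulus(10000, seed=int(seeds[1]))
        m = NeuronModel(kind="tuned", pref_ori=1.0, pref_sf=4.0, kappa=2.5,
                        sf_sigma=0.35, baseline=2.0, max_rate=50.0)
        _, counts, _ = simulate_neuron(m, g, trace, seed=int(seeds[2]))
        out = forward_correlation_temporal(g, counts, self._fit(), n_lags=8)
        kernel_peak = int(np.argmax(m.temporal_kernel))
        assert abs(int(np.nanargmax(out["preferred"])) - kernel_peak) <= 1
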