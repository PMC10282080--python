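"""Generator contracts: determinism, kinematics, stimulus statistics,
Poisson spiking."""
import numpy as np
import pytest
from scipy import stats

from fvrf.datatypes import TrackerNoiseSpec
from fvrf.simulate import (
    NeuronModel,
    OpticsSpec,
    apply_tracker_noise,
    gen_dot_stimulus,
    gen_eye_trace,
    gen_grating_stimulus,
    gen_motion_dot_stimulus,
    render_eye_camera_frames,
    simulate_neuron,
)


class TestEyeTrace:
    def test_no_motion_sources_constant_trace(self):
        trace, sacs = gen_eye_trace(2.0, drift_sd=0.0, saccade_rate=0.0, seed=0)
        assert sacs == []
        assert np.allclose(trace.x, 0.0) and np.allclose(trace.y, 0.0)

    def test_saccade_count_and_kinematics(self, short_trace):
        _, sacs = short_trace
        # ~2/s over 20 s, allowing for refractory fixation minimum
        assert 20 <= len(sacs) <= 60
        for s in sacs:
            assert s.peak_velocity > 8.0
            assert s.amplitude >= 1.0
            # minimum-jerk peak speed: 1.875 * amplitude / duration
            T = s.t_end - s.t_start
            assert np.isclose(s.peak_velocity, 1.875 * s.amplitude / T, rtol=1e-6)

    def test_numeric_peak_velocity_matches_analytic(self):
        trace, sacs = gen_eye_trace(10.0, drift_sd=0.0, saccade_rate=2.0, seed=3)
        v = np.hypot(np.diff(trace.x), np.diff(trace.y)) * trace.rate
        for s in sacs:
            win = (trace.t[:-1] >= s.t_start) & (trace.t[:-1] <= s.t_end)
            assert abs(v[win].max() - s.peak_velocity) / s.peak_velocity < 0.05

    def test_determinism(self):
        t1, s1 = gen_eye_trace(5.0, seed=42)
        t2, s2 = gen_eye_trace(5.0, seed=42)
        assert np.array_equal(t1.x, t2.x) and np.array_equal(t1.y, t2.y)
        assert len(s1) == len(s2)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            gen_eye_trace(0.0)
        with pytest.raises(ValueError):
            gen_eye_trace(5.0, rate=100.0)
        with pytest.raises(ValueError):
            gen_eye_trace(5.0, amplitude_range=(100.0, 200.0))


class TestTrackerNoise:
    def test_identity_spec(self, short_trace):
        trace, _ = short_trace
        out = apply_tracker_noise(trace, TrackerNoiseSpec(0.0, 1.0), seed=0)
        assert np.array_equal(out.x, trace.x)
        assert np.array_equal(out.y, trace.y)

    def test_gain_is_multiplicative_about_center(self, short_trace):
        trace, _ = short_trace
        out = apply_tracker_noise(trace, TrackerNoiseSpec(0.0, 1.1), seed=0)
        assert np.allclose(out.x, 1.1 * trace.x)

    def test_precision_noise_sd(self, short_trace):
        trace, _ = short_trace
        out = apply_tracker_noise(trace, TrackerNoiseSpec(0.1, 1.0), seed=5)
        resid = out.x - trace.x
        assert abs(resid.std() - 0.1) < 0.005  # 2e4 samples

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TrackerNoiseSpec(precision_sd=-1.0)
        with pytest.raises(ValueError):
            TrackerNoiseSpec(gain=0.0)


class TestDots:
    def test_one_dot_per_frame(self):
        d = gen_dot_stimulus(50, dots_per_frame=1, seed=0)
        assert d.x.shape == (50, 1)

    def test_polarity_balance(self):
        d = gen_dot_stimulus(1000, dots_per_frame=10, seed=1)
        n_white = (d.polarity > 0).sum()
        # binomial two-sided check at alpha=1e-3, n=1e4
        p = stats.binomtest(int(n_white), 10000, 0.5).pvalue
        assert p > 1e-3

    def test_replay_bit_exact(self, tmp_path):
        d = gen_dot_stimulus(100, dots_per_frame=5, seed=9)
        d2 = gen_dot_stimulus(100, dots_per_frame=5, seed=9)
        assert np.array_equal(d.x, d2.x) and np.array_equal(d.polarity, d2.polarity)
        path = tmp_path / "dots.jsonl"
        d.to_jsonl(path)
        d3 = type(d).from_jsonl(path)
        assert np.allclose(d3.x, d.x) and np.array_equal(d3.polarity, d.polarity)


class TestGratings:
    def test_blank_fraction_and_contrast(self):
        g = gen_grating_stimulus(10000, blank_prob=0.3, seed=2)
        assert g.contrast == 0.25  # default, 25% contrast
        assert abs(g.blank.mean() - 0.3) < 0.02
        g0 = gen_grating_stimulus(500, blank_prob=0.0, seed=2)
        assert not g0.blank.any()

    def test_blank_prob_bound(self):
        with pytest.raises(ValueError):
            gen_grating_stimulus(10, blank_prob=0.7)


class TestMotionDots:
    def test_default_direction_spacing(self, small_motion):
        d = np.diff(small_motion.directions)
        assert small_motion.directions.size == 16
        assert np.allclose(np.degrees(d), 22.5)

    def test_age_cycles_and_displacement(self, small_motion):
        m = small_motion
        assert m.age.max() == m.lifetime - 1
        # surviving dots move exactly speed/frame_rate along their direction
        step = m.speed / m.frame_rate
        alive = m.age[1:] > 0
        dx = (m.x[1:] - m.x[:-1])[alive]
        expect = step * np.cos(m.directions[m.dir_idx[1:][alive]])
        assert np.allclose(dx, expect, atol=1e-9)
        # replotted dots have age 0 and a full lifetime ahead
        replot = m.age[1:] == 0
        assert replot.any()

    def test_direction_histogram_uniform(self):
        m = gen_motion_dot_stimulus(3000, seed=8)
        # count at replot events (independent draws)
        new = m.dir_idx[m.age == 0]
        obs = np.bincount(new, minlength=16)
        chi2 = ((obs - obs.mean()) ** 2 / obs.mean()).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=15)

    def test_dot_count_conserved(self, small_motion):
        assert small_motion.x.shape[1] == small_motion.max_dots
        assert np.isfinite(small_motion.x).all()


class TestNeurons:
    def test_zero_contrast_baseline(self, short_trace):
        trace, _ = short_trace
        g = gen_grating_stimulus(1200, contrast=0.0, seed=0)
        m = NeuronModel(kind="tuned", baseline=5.0, max_rate=40.0)
        _, counts, rate = simulate_neuron(m, g, trace, seed=1)
        assert np.allclose(rate, 5.0)

    def test_half_squaring_quadruples_drive(self):
        # doubling a suprathreshold drive quadruples the rate increment
        m = NeuronModel(kind="simple", center=(0, 0), sigma=0.5, baseline=0.0,
                        gain=1.0)
        v1 = m.filter_value(np.array([0.1]), np.array([0.0]))
        assert np.isclose((2 * v1) ** 2 / v1**2, 4.0)

    def test_mt_direction_preference(self, small_motion, short_trace):
        trace, _ = short_trace
        rates = {}
        for pref in (np.pi / 2, 3 * np.pi / 2):
            m = NeuronModel(kind="mt", center=(0, 0), pref_dir=np.pi / 2,
                            dir_kappa=3.0, envelope_sigma=2.0, baseline=1.0,
                            gain=10.0)
            # coherent motion: force all dots to one direction index
            mot = small_motion
            idx_up = int(np.argmin(np.abs(mot.directions - pref)))
            mot2 = type(mot)(
                frame_times=mot.frame_times, x=mot.x, y=mot.y,
                dir_idx=np.full_like(mot.dir_idx, idx_up), age=mot.age,
                directions=mot.directions, speed=mot.speed,
                lifetime=mot.lifetime, dot_size=mot.dot_size,
                frame_rate=mot.frame_rate, screen=mot.screen,
            )
            _, _, rate = simulate_neuron(m, mot2, trace, seed=2)
            rates[pref] = rate.mean()
        assert rates[np.pi / 2] > 2 * rates[3 * np.pi / 2]

    def test_poisson_fano_factor(self, short_trace):
        trace, _ = short_trace
        g = gen_grating_stimulus(600, seed=4)
        m = NeuronModel(kind="tuned", baseline=20.0, max_rate=20.0)
        totals = []
        for seed in range(60):
            _, counts, _ = simulate_neuron(m, g, trace, seed=seed)
            totals.append(counts.sum())
        totals = np.array(totals)
        fano = totals.var(ddof=1) / totals.mean()
        assert 0.6 < fano < 1.6  # Poisson: 1, binomial tolerance at n=60

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            NeuronModel(kind="simple", baseline=-1.0)


class TestCamera:
    def test_zero_rotation_reference_and_threshold(self):
        frames, gt = render_eye_camera_frames(np.array([[0.0, 0.0]]))
        o = gt["optics"]
        assert np.allclose(gt["p1"][0], o.p1_ref)
        assert frames[0].max() > 200  # P1 bright enough for threshold stage

    def test_centroid_oracle_on_noiseless_frames(self):
        rots = np.array([[1.0, -0.5], [-2.0, 1.5]])
        frames, gt = render_eye_camera_frames(rots)
        for i in range(2):
            img = frames[i].astype(float)
            # oracle: intensity centroid of the P1 region
            rows, cols = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
            m = img > 150
            r = (img * m * rows).sum() / (img * m).sum()
            c = (img * m * cols).sum() / (img * m).sum()
            assert abs(r - gt["p1"][i][0]) < 0.1
            assert abs(c - gt["p1"][i][1]) < 0.1
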