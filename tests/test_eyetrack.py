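"""Eye tracking: Purkinje localization, calibration refinement, saccade
detection and the post-saccadic analysis mask."""
import numpy as np
import pytest

from fvrf.datatypes import EyeTrace, TrackerNoiseSpec
from fvrf.eyetrack import (
    SaccadeEvent,
    analysis_mask,
    detect_saccades,
    refine_calibration_bilinear,
    track_purkinje,
)
from fvrf.simulate import (
    OpticsSpec,
    apply_tracker_noise,
    gen_eye_trace,
    render_eye_camera_frames,
)


class TestPurkinje:
    def test_noiseless_localization_within_tenth_pixel(self):
        rots = np.column_stack([np.linspace(-2, 2, 9), np.linspace(1, -1, 9)])
        frames, gt = render_eye_camera_frames(rots)
        trk = track_purkinje(frames)
        assert trk.valid.all()
        assert np.abs(trk.p1 - gt["p1"]).max() < 0.1
        assert np.abs(trk.p4 - gt["p4"]).max() < 0.1

    def test_dark_frame_flagged_invalid(self):
        trk = track_purkinje(np.zeros((2, 96, 128), dtype=np.uint8))
        assert not trk.valid.any()
        assert np.isnan(trk.displacement).all()

    def test_displacement_linear_in_rotation(self):
        rots = np.column_stack([np.linspace(-2.5, 2.5, 15), np.zeros(15)])
        frames, gt = render_eye_camera_frames(rots)
        trk = track_purkinje(frames)
        r2 = np.corrcoef(rots[:, 0], trk.displacement[:, 0])[0, 1] ** 2
        assert r2 > 0.99
        slope = np.polyfit(rots[:, 0], trk.displacement[:, 0], 1)[0]
        assert np.isclose(slope, gt["optics"].displacement_gain, rtol=0.02)

    def test_noise_degrades_gracefully(self):
        rots = np.zeros((3, 2))
        frames, _ = render_eye_camera_frames(rots, OpticsSpec(noise_sd=8.0),
                                             seed=3)
        trk = track_purkinje(frames)  # must not raise
        assert trk.p1.shape == (3, 2)


class TestBilinearCalibration:
    def grid(self):
        g = np.arange(-6, 7, 3.0)
        return np.array([(x, y) for x in g for y in g])

    def test_identity_input_recovers_identity(self):
        targets = self.grid()
        p = refine_calibration_bilinear(targets, targets)
        assert abs(p.gain_x - 1) < 1e-9 and abs(p.gain_y - 1) < 1e-9
        assert abs(p.offset_x) < 1e-9 and abs(p.offset_y) < 1e-9

    def test_recovers_injected_offset_and_gain(self):
        targets = self.grid()
        # tracker reports raw = g*true + o; fixations land on targets
        g, ox, oy = 1.08, 0.5, -0.3
        raw = np.column_stack([g * targets[:, 0] + ox, g * targets[:, 1] + oy])
        p = refine_calibration_bilinear(raw, targets)
        gx, gy = p.implied_tracker_gain
        tx, ty = p.implied_tracker_offset
        assert np.allclose([gx, gy], g, atol=1e-9)
        assert np.allclose([tx, ty], [ox, oy], atol=1e-9)

    def test_composes_with_tracker_noise_model(self):
        trace, _ = gen_eye_trace(2.0, drift_sd=0.0, saccade_rate=0.0, seed=0)
        spec = TrackerNoiseSpec(precision_sd=0.0, gain=1.15)
        targets = self.grid()
        raw = np.column_stack([spec.gain * targets[:, 0],
                               spec.gain * targets[:, 1]])
        p = refine_calibration_bilinear(raw, targets, match_radius=2.0)
        assert np.allclose(p.implied_tracker_gain, spec.gain, atol=1e-12)

    def test_far_fixation_contributes_nothing(self):
        targets = self.grid()
        fix = np.vstack([targets, [[20.0, 20.0]]])  # 1.5+ d.v.a from any target
        p1 = refine_calibration_bilinear(fix, targets)
        p2 = refine_calibration_bilinear(targets, targets)
        assert np.isclose(p1.gain_x, p2.gain_x) and p1.n_pairs == p2.n_pairs

    def test_too_few_matches_rejected(self):
        with pytest.raises(ValueError):
            refine_calibration_bilinear(np.array([[0, 0], [1, 1]]),
                                        np.array([[0, 0], [1, 1]]))


class TestSaccadeDetector:
    def test_constant_trace_empty(self):
        trace, _ = gen_eye_trace(3.0, drift_sd=0.0, saccade_rate=0.0, seed=0)
        assert detect_saccades(trace) == []

    def test_subthreshold_velocity_rejected(self):
        # slow ramp: 4 deg/s constant velocity never crosses 8 deg/s
        t = np.arange(0, 3.0, 1e-3)
        trace = EyeTrace(t, 4.0 * t, np.zeros_like(t), 1000.0)
        assert detect_saccades(trace) == []

    def test_injected_saccades_recovered_with_timing(self):
        trace, sacs = gen_eye_trace(20.0, drift_sd=0.02, saccade_rate=0.5,
                                    amplitude_range=(1.0, 5.0), seed=21)
        events = detect_saccades(trace)
        assert len(events) == len(sacs)
        for s in sacs:
            e = min(events, key=lambda e: abs(e.t_peak - s.t_peak))
            assert abs(e.t_start - s.t_start10) < 0.005
            assert abs(e.t_end - s.t_end10) < 0.005

    def test_recall_precision_over_seeded_suite(self):
        hits = fps = n_gt = n_det = 0
        for seed in range(20):
            trace, sacs = gen_eye_trace(20.0, drift_sd=0.05, saccade_rate=2.0,
                                        seed=seed)
            events = detect_saccades(trace)
            gt = np.array([s.t_peak for s in sacs])
            det = np.array([e.t_peak for e in events])
            hits += sum(np.abs(det - g).min() < 0.03 for g in gt)
            fps += sum(np.abs(gt - d).min() > 0.03 for d in det)
            n_gt += len(gt)
            n_det += len(det)
        assert hits == n_gt  # recall 1.0
        assert fps == 0  # precision 1.0

    def test_event_invariants(self):
        with pytest.raises(ValueError):
            SaccadeEvent(t_start=1.0, t_end=0.9, t_peak=0.95,
                         peak_velocity=50.0, amplitude=2.0)


class TestAnalysisMask:
    def test_no_saccades_all_true(self):
        times = np.arange(0, 1, 0.01)
        assert analysis_mask(times, []).all()

    def test_exclusion_window(self):
        times = np.arange(0, 2, 0.001)
        sac = SaccadeEvent(t_start=0.9, t_end=1.0, t_peak=0.95,
                           peak_velocity=100.0, amplitude=2.0)
        mask = analysis_mask(times, [sac], post_saccade_exclusion_ms=50.0)
        assert not mask[(times >= 0.9) & (times <= 1.05)].any()
        assert mask[times < 0.899].all() and mask[times > 1.051].all()

    def test_zero_exclusion_masks_only_span(self):
        times = np.arange(0, 2, 0.001)
        sac = SaccadeEvent(t_start=0.9, t_end=1.0, t_peak=0.95,
                           peak_velocity=100.0, amplitude=2.0)
        mask = analysis_mask(times, [sac], post_saccade_exclusion_ms=0.0)
        assert mask[times > 1.0005].all()
        assert not mask[(times >= 0.9) & (times <= 1.0)].any()
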