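"""Gaze-contingent binning, velocity decomposition and ROI reconstruction."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fvrf.datatypes import DotStimulus, EyeTrace
from fvrf.gazestim import (
    Grid,
    ROISpec,
    bin_dots_gaze_contingent,
    decompose_velocity,
    reconstruct_roi_movie,
)
from fvrf.simulate import gen_dot_stimulus, gen_eye_trace, gen_motion_dot_stimulus


def _static_trace(duration=10.0, x=0.0, y=0.0, rate=1000.0):
    t = np.arange(0, duration, 1 / rate)
    return EyeTrace(t, np.full_like(t, x), np.full_like(t, y), rate)


def _single_dot(x, y, pol=1.0, n=1, frame_rate=60.0, screen=(28.0, 16.0)):
    return DotStimulus(
        frame_times=np.arange(n) / frame_rate,
        x=np.full((n, 1), x), y=np.full((n, 1), y),
        polarity=np.full((n, 1), pol),
        dot_size=0.5, frame_rate=frame_rate, screen=screen,
    )


class TestGrid:
    def test_default_coarse_grid(self):
        g = Grid.centered()
        assert (g.nx, g.ny) == (28, 16)  # 28 x 16 d.v.a at 1 d.v.a spacing
        assert g.spacing == 1.0

    def test_half_open_assignment(self):
        g = Grid.centered((4, 4), 1.0)
        # boundary between cells: lower edge belongs to the cell
        flat, ok = g.assign(np.array([-1.0, 0.0]), np.array([0.0, 0.0]))
        assert ok.all()
        assert flat[0] != flat[1]


class TestBinning:
    def test_dot_at_gaze_center_cell(self):
        g = Grid.centered((5, 5), 1.0)
        trace = _static_trace()
        dots = _single_dot(0.0, 0.0)
        b = bin_dots_gaze_contingent(dots, trace, g)
        row = b.X.toarray()[0]
        center = (g.ny // 2) * g.nx + g.nx // 2
        assert row[center] == 1 and row.sum() == 1

    def test_out_of_extent_all_zero(self):
        g = Grid.centered((5, 5), 1.0)
        b = bin_dots_gaze_contingent(_single_dot(10.0, 0.0), _static_trace(), g)
        assert b.X.nnz == 0

    def test_brute_force_oracle_and_mass_conservation(self, small_dots):
        trace, _ = gen_eye_trace(10.0, seed=5)
        g = Grid.centered((10, 8), 1.0)
        b = bin_dots_gaze_contingent(small_dots, trace, g)
        X = b.X.toarray()
        gx, gy = trace.position_at(small_dots.frame_times)
        n_in = np.zeros(small_dots.n_frames)
        Xo = np.zeros_like(X)
        for t in range(small_dots.n_frames):
            for i in range(small_dots.dots_per_frame):
                rx = small_dots.x[t, i] - gx[t]
                ry = small_dots.y[t, i] - gy[t]
                ix = int(np.floor((rx - (g.x_centers[0] - 0.5))))
                iy = int(np.floor((ry - (g.y_centers[0] - 0.5))))
                if 0 <= ix < g.nx and 0 <= iy < g.ny:
                    Xo[t, iy * g.nx + ix] += 1
                    n_in[t] += 1
        assert np.array_equal(X, Xo)
        assert np.array_equal(X.sum(axis=1), n_in)

    def test_signed_binning_uses_polarity(self):
        g = Grid.centered((5, 5), 1.0)
        b = bin_dots_gaze_contingent(_single_dot(0.0, 0.0, pol=-1.0),
                                     _static_trace(), g, ignore_sign=False)
        assert b.X.toarray().min() == -1

    @settings(max_examples=20, deadline=None)
    @given(st.integers(-2, 2), st.integers(-2, 2))
    def test_translation_equivariance(self, sx, sy):
        """Shifting all dots by whole cells shifts the binned pattern."""
        g = Grid.centered((12, 12), 1.0)
        trace = _static_trace(1.0)
        d1 = _single_dot(0.3, -0.2)
        d2 = _single_dot(0.3 + sx, -0.2 + sy)
        r1 = bin_dots_gaze_contingent(d1, trace, g).X.toarray()[0].reshape(12, 12)
        r2 = bin_dots_gaze_contingent(d2, trace, g).X.toarray()[0].reshape(12, 12)
        flat, _ = g.assign(np.array([0.3]), np.array([-0.2]))
        iy, ix = divmod(flat[0], g.nx)
        assert r1[iy, ix] == 1
        assert r2[iy + sy, ix + sx] == 1

    def test_uncovered_frames_dropped(self):
        trace = _static_trace(duration=0.5)
        dots = _single_dot(0.0, 0.0, n=60)  # 1 s of frames, 0.5 s of trace
        b = bin_dots_gaze_contingent(dots, trace, Grid.centered((5, 5), 1.0))
        assert b.n_dropped > 0
        assert b.X[-1].nnz == 0


class TestVelocity:
    def test_single_dot_moving_right(self):
        mot = gen_motion_dot_stimulus(3, max_dots=1, n_dirs=4, lifetime=100,
                                      seed=0)
        mot.dir_idx[:] = 0  # direction 0 rad = rightward
        mot.age[:] = np.arange(3)[:, None] + 1  # never replotted
        g = Grid.centered((28, 16), 2.0)
        v = decompose_velocity(mot, _static_trace(), g)
        row = v.Vx.toarray()[1]
        assert np.isclose(row.sum(), 15.0)  # 15 d.v.a/s horizontal
        assert v.Vy.toarray()[1].sum() == 0

    def test_replot_contributes_nothing(self):
        mot = gen_motion_dot_stimulus(3, max_dots=1, lifetime=100, seed=0)
        mot.age[:] = 0  # treated as replotted on every frame
        v = decompose_velocity(mot, _static_trace(), Grid.centered((28, 16), 2.0))
        assert v.Vx.nnz == 0 and v.Vy.nnz == 0

    def test_channel_sums_match_brute_force(self, small_motion):
        trace, _ = gen_eye_trace(10.0, seed=6)
        g = Grid.centered((16, 10), 2.0)
        v = decompose_velocity(small_motion, trace, g)
        m = small_motion
        gx, gy = trace.position_at(m.frame_times)
        t = 101
        vx_expect = np.zeros(g.n_cells)
        for i in range(m.max_dots):
            if m.age[t, i] == 0:
                continue
            rx, ry = m.x[t, i] - gx[t], m.y[t, i] - gy[t]
            flat, ok = g.assign(np.array([rx]), np.array([ry]))
            if ok[0]:
                vx_expect[flat[0]] += m.speed * np.cos(m.directions[m.dir_idx[t, i]])
        assert np.allclose(v.Vx.toarray()[t], vx_expect)


class TestROIMovie:
    def test_default_roi_spec(self):
        roi = ROISpec()
        assert roi.shape == (70, 70)
        assert roi.pitch_arcmin == 1.6

    def test_dot_rendered_at_expected_pixel(self):
        roi = ROISpec(shape=(21, 21), pitch_arcmin=3.0)
        dots = _single_dot(0.0, 0.0, n=1, screen=(12.0, 12.0))
        mov = reconstruct_roi_movie(dots, _static_trace(), roi)
        # dot at gaze center -> peak at the central pixel
        r, c = np.unravel_index(np.argmax(mov.movie[0]), (21, 21))
        assert (r, c) == (10, 10)
        assert np.isclose(mov.movie[0, 10, 10], 1.0, atol=1e-6)

    def test_seeded_replay_identical(self):
        dots = gen_dot_stimulus(20, 50, dot_size=0.2, seed=3,
                                screen=(12.0, 12.0))
        trace, _ = gen_eye_trace(1.0, seed=4, screen=(12.0, 12.0),
                                 bounds_frac=0.5)
        roi = ROISpec(shape=(15, 15), pitch_arcmin=3.0)
        m1 = reconstruct_roi_movie(dots, trace, roi)
        m2 = reconstruct_roi_movie(dots, trace, roi)
        assert np.array_equal(m1.movie, m2.movie)

    def test_zero_calibration_grid_is_identity(self):
        from fvrf.calibnet import CalibrationGrid

        dots = gen_dot_stimulus(10, 50, dot_size=0.2, seed=3,
                                screen=(12.0, 12.0))
        trace, _ = gen_eye_trace(1.0, seed=4, screen=(12.0, 12.0),
                                 bounds_frac=0.5)
        roi = ROISpec(shape=(15, 15), pitch_arcmin=3.0)
        nodes = np.arange(-5.0, 5.5, 1.0)
        zero = CalibrationGrid(nodes, np.zeros((11, 11)), np.zeros((11, 11)))
        m1 = reconstruct_roi_movie(dots, trace, roi)
        m2 = reconstruct_roi_movie(dots, trace, roi, calibration_grid=zero)
        assert np.array_equal(m1.movie, m2.movie)

    def test_offscreen_roi_flagged(self):
        dots = _single_dot(0.0, 0.0, n=1, screen=(4.0, 4.0))
        trace = _static_trace(x=1.9, y=0.0)
        mov = reconstruct_roi_movie(dots, trace,
                                    ROISpec(shape=(15, 15), pitch_arcmin=3.0))
        assert mov.clipped[0]
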