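"""Stimulus generators: sparse flashed dots, full-field flashed gratings, and
sparse motion-dot noise.  All are replayable bit-exactly from their seed."""
from __future__ import annotations

import numpy as np

from ..datatypes import DotStimulus, GratingStimulus, MotionDotStimulus

__all__ = ["gen_dot_stimulus", "gen_grating_stimulus", "gen_motion_dot_stimulus"]


def gen_dot_stimulus(
    n_frames: int,
    dots_per_frame: int = 10,
    dot_size: float = 0.5,
    frame_rate: float = 60.0,
    seed: int | None = 0,
    screen: tuple[float, float] = (28.0, 16.0),
) -> DotStimulus:
    """Full-field sparse noise: ``dots_per_frame`` full-contrast dots per
    frame, each at an independent uniform screen position with equiprobable
    white (+1) or black (-1) polarity."""
    if dots_per_frame < 1:
        raise ValueError("dots_per_frame must be >= 1")
    rng = np.random.default_rng(seed)
    w, h = screen
    x = rng.uniform(-w / 2, w / 2, size=(n_frames, dots_per_frame))
    y = rng.uniform(-h / 2, h / 2, size=(n_frames, dots_per_frame))
    pol = rng.choice([-1.0, 1.0], size=(n_frames, dots_per_frame))
    return DotStimulus(
        frame_times=np.arange(n_frames) / frame_rate,
        x=x,
        y=y,
        polarity=pol,
        dot_size=dot_size,
        frame_rate=frame_rate,
        screen=screen,
        seed=seed,
    )


def gen_grating_stimulus(
    n_frames: int,
    orientations: np.ndarray | None = None,
    spatial_freqs: np.ndarray | None = None,
    contrast: float = 0.25,
    blank_prob: float = 0.25,
    frame_rate: float = 60.0,
    seed: int | None = 0,
) -> GratingStimulus:
    """Full-field flashed gratings on a polar grid of orientation x spatial
    frequency, updated randomly every frame; a ``blank_prob`` fraction of
    frames is a blank gray background.

    Defaults: 25% contrast; 12 orientations over [0, pi); spatial frequencies
    log-spaced over 1-16 cyc/deg.
    """
    if not 0.0 <= blank_prob <= 0.5:
        raise ValueError("blank_prob must be in [0, 0.5]")
    if orientations is None:
        orientations = np.arange(12) * np.pi / 12
    if spatial_freqs is None:
        spatial_freqs = np.geomspace(1.0, 16.0, 8)
    rng = np.random.default_rng(seed)
    blank = rng.random(n_frames) < blank_prob
    ori = np.asarray(orientations)[rng.integers(0, len(orientations), n_frames)]
    sf = np.asarray(spatial_freqs)[rng.integers(0, len(spatial_freqs), n_frames)]
    phase = rng.uniform(0.0, 2 * np.pi, n_frames)
    ori[blank] = np.nan
    sf[blank] = np.nan
    phase[blank] = np.nan
    return GratingStimulus(
        frame_times=np.arange(n_frames) / frame_rate,
        orientation=ori,
        spatial_freq=sf,
        phase=phase,
        blank=blank,
        contrast=contrast,
        frame_rate=frame_rate,
        seed=seed,
    )


def gen_motion_dot_stimulus(
    n_frames: int,
    frame_rate: float = 100.0,
    max_dots: int = 32,
    speed: float = 15.0,
    n_dirs: int = 16,
    lifetime: int = 5,
    dot_size: float = 0.5,
    seed: int | None = 0,
    screen: tuple[float, float] = (28.0, 16.0),
) -> MotionDotStimulus:
    """Sparse motion noise: ``max_dots`` white dots drifting at ``speed``
    d.v.a/s in one of ``n_dirs`` uniformly spaced directions, replotted at a
    uniform random position (with a fresh random direction) every ``lifetime``
    frames.  Replot schedules are staggered across dots (asynchronous
    updating); a replotted dot contributes no displacement on that frame
    transition.
    """
    if lifetime < 1:
        raise ValueError("lifetime must be >= 1")
    rng = np.random.default_rng(seed)
    w, h = screen
    directions = np.arange(n_dirs) * 2 * np.pi / n_dirs
    step = speed / frame_rate

    x = np.empty((n_frames, max_dots))
    y = np.empty((n_frames, max_dots))
    dir_idx = np.empty((n_frames, max_dots), dtype=np.int64)
    age = np.empty((n_frames, max_dots), dtype=np.int64)

    x[0] = rng.uniform(-w / 2, w / 2, max_dots)
    y[0] = rng.uniform(-h / 2, h / 2, max_dots)
    dir_idx[0] = rng.integers(0, n_dirs, max_dots)
    age[0] = rng.integers(0, lifetime, max_dots)  # stagger replot schedule

    for t in range(1, n_frames):
        # survivors drift; expired or off-screen dots replot with a fresh
        # direction (a replot contributes no displacement, so downstream
        # velocity decomposition can trust displacement = step * direction)
        dx = step * np.cos(directions[dir_idx[t - 1]])
        dy = step * np.sin(directions[dir_idx[t - 1]])
        x[t] = x[t - 1] + dx
        y[t] = y[t - 1] + dy
        dir_idx[t] = dir_idx[t - 1]
        age[t] = age[t - 1] + 1
        replot = (
            (age[t] >= lifetime)
            | (np.abs(x[t]) > w / 2)
            | (np.abs(y[t]) > h / 2)
        )
        n_new = int(replot.sum())
        if n_new:
            x[t, replot] = rng.uniform(-w / 2, w / 2, n_new)
            y[t, replot] = rng.uniform(-h / 2, h / 2, n_new)
            dir_idx[t, replot] = rng.integers(0, n_dirs, n_new)
            age[t, replot] = 0
    return MotionDotStimulus(
        frame_times=np.arange(n_frames) / frame_rate,
        x=x,
        y=y,
        dir_idx=dir_idx,
        age=age,
        directions=directions,
        speed=speed,
        lifetime=lifetime,
        dot_size=dot_size,
        frame_rate=frame_rate,
        screen=screen,
        seed=seed,
    )
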