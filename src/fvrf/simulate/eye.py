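"""Synthetic eye traces: fixational drift plus minimum-jerk saccades, and the
tracker error model (precision noise, calibration gain, smooth warp).

The saccade profile is a minimum-jerk position trajectory with duration
T = 20 + 2*amplitude ms, which yields main-sequence-like kinematics: peak
velocity 1.875*A/T and peak acceleration (10/sqrt(3))*A/T^2, so a 1 d.v.a.
saccade peaks near 85 deg/s and 1.2e4 deg/s^2 — comfortably above the
velocity/acceleration detector thresholds — while fixational drift stays far
below them for reasonable diffusion constants.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ..datatypes import EyeTrace, TrackerNoiseSpec

__all__ = ["GroundTruthSaccade", "gen_eye_trace", "apply_tracker_noise"]

# minimum-jerk normalized position s(u) = 10u^3 - 15u^4 + 6u^5, u in [0, 1]
_MJ_VPEAK = 1.875  # max of s'(u)
_MJ_APEAK = 10.0 / np.sqrt(3.0)  # max of |s''(u)|


def _mj_pos(u: np.ndarray) -> np.ndarray:
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def _mj_speed(u: np.ndarray) -> np.ndarray:
    """s'(u) = 30 u^2 (1-u)^2."""
    return 30.0 * u**2 * (1.0 - u) ** 2


@dataclass
class GroundTruthSaccade:
    """Bookkeeping for one injected saccade.

    ``t_start10`` / ``t_end10`` are the analytic times at which the speed
    profile crosses 10 deg/s (the detector's start/end criterion); they are
    NaN when peak velocity never reaches 10 deg/s.
    """

    t_start: float
    t_end: float
    t_peak: float
    amplitude: float
    peak_velocity: float
    peak_acceleration: float
    t_start10: float
    t_end10: float
    x0: float
    y0: float
    x1: float
    y1: float


def saccade_duration(amplitude: float) -> float:
    """Main-sequence duration model: 20 ms + 2 ms per d.v.a."""
    return 0.020 + 0.002 * amplitude


def _threshold_crossings(amplitude: float, T: float, v_thr: float = 10.0):
    """Analytic times (relative to saccade onset) where speed crosses v_thr."""
    vpeak = _MJ_VPEAK * amplitude / T
    if vpeak <= v_thr:
        return np.nan, np.nan
    f = lambda u: 30.0 * amplitude / T * (u**2 * (1.0 - u) ** 2) - v_thr
    u_lo = brentq(f, 1e-9, 0.5)
    u_hi = brentq(f, 0.5, 1.0 - 1e-9)
    return u_lo * T, u_hi * T


def gen_eye_trace(
    duration: float,
    rate: float = 1000.0,
    drift_sd: float = 0.05,
    saccade_rate: float = 2.0,
    amplitude_range: tuple[float, float] = (1.0, 8.0),
    seed: int | None = 0,
    screen: tuple[float, float] = (28.0, 16.0),
    bounds_frac: float = 0.8,
) -> tuple[EyeTrace, list[GroundTruthSaccade]]:
    """Generate a fixation/saccade eye trace with ground-truth saccade list.

    Parameters
    ----------
    duration : trace length, s (> 0)
    rate : sampling rate, Hz (>= 500 so saccade kinematics are resolvable)
    drift_sd : Brownian fixational-drift diffusion, d.v.a. per sqrt(s)
    saccade_rate : mean saccades per second (exponential fixation durations)
    amplitude_range : (min, max) saccade amplitude, d.v.a.
    screen, bounds_frac : gaze is kept within ``bounds_frac`` of the screen

    Returns
    -------
    (EyeTrace, list[GroundTruthSaccade])
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if rate < 500:
        raise ValueError("rate must be >= 500 Hz")
    lo, hi = amplitude_range
    bx = 0.5 * screen[0] * bounds_frac
    by = 0.5 * screen[1] * bounds_frac
    if lo > np.hypot(2 * bx, 2 * by):
        raise ValueError("amplitude_range incompatible with screen bounds")

    rng = np.random.default_rng(seed)
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    x = np.zeros(n)
    y = np.zeros(n)
    saccades: list[GroundTruthSaccade] = []

    pos = np.array([0.0, 0.0])
    i = 0
    while i < n - 1:
        # --- fixation segment -------------------------------------------
        if saccade_rate > 0:
            fix_dur = max(rng.exponential(1.0 / saccade_rate), 0.08)
        else:
            fix_dur = duration + 1.0
        n_fix = min(int(round(fix_dur * rate)), n - 1 - i)
        if n_fix > 0:
            steps = rng.normal(0.0, drift_sd / np.sqrt(rate), size=(n_fix, 2))
            walk = np.empty((n_fix, 2))
            # clamp at the allowed box so drift cannot escape
            walk[:, 0] = np.clip(pos[0] + np.cumsum(steps[:, 0]), -bx, bx)
            walk[:, 1] = np.clip(pos[1] + np.cumsum(steps[:, 1]), -by, by)
            x[i + 1 : i + 1 + n_fix] = walk[:, 0]
            y[i + 1 : i + 1 + n_fix] = walk[:, 1]
            pos = walk[-1].copy()
            i += n_fix
        if i >= n - 1 or saccade_rate <= 0:
            break
        # --- saccade ----------------------------------------------------
        for _ in range(200):
            amp = rng.uniform(lo, hi)
            ang = rng.uniform(0.0, 2 * np.pi)
            target = pos + amp * np.array([np.cos(ang), np.sin(ang)])
            if abs(target[0]) <= bx and abs(target[1]) <= by:
                break
        else:  # pragma: no cover - extremely unlikely
            target = np.array([0.0, 0.0])
            amp = float(np.hypot(*(target - pos)))
        T = saccade_duration(amp)
        n_sac = max(int(round(T * rate)), 4)
        u = np.arange(1, n_sac + 1) / n_sac
        prof = _mj_pos(u)
        seg = pos[None, :] + (target - pos)[None, :] * prof[:, None]
        n_sac = min(n_sac, n - 1 - i)
        x[i + 1 : i + 1 + n_sac] = seg[:n_sac, 0]
        y[i + 1 : i + 1 + n_sac] = seg[:n_sac, 1]
        t_on = t[i]
        d10_lo, d10_hi = _threshold_crossings(amp, T)
        saccades.append(
            GroundTruthSaccade(
                t_start=t_on,
                t_end=t_on + T,
                t_peak=t_on + 0.5 * T,
                amplitude=amp,
                peak_velocity=_MJ_VPEAK * amp / T,
                peak_acceleration=_MJ_APEAK * amp / T**2,
                t_start10=t_on + d10_lo if np.isfinite(d10_lo) else np.nan,
                t_end10=t_on + d10_hi if np.isfinite(d10_hi) else np.nan,
                x0=pos[0],
                y0=pos[1],
                x1=target[0],
                y1=target[1],
            )
        )
        pos = target.copy()
        i += n_sac

    # drop a trailing ground-truth saccade that was truncated by the trace end
    if saccades and saccades[-1].t_end > t[-1]:
        saccades.pop()
    return EyeTrace(t, x, y, rate), saccades


def apply_tracker_noise(
    trace: EyeTrace, spec: TrackerNoiseSpec, seed: int | None = 0
) -> EyeTrace:
    """Corrupt a true eye trace the way a real tracker would.

    reported = gain * true + warp(true) + N(0, precision_sd^2) per sample.
    The input (ground truth) is left untouched.
    """
    rng = np.random.default_rng(seed)
    x = spec.gain * trace.x
    y = spec.gain * trace.y
    if spec.warp is not None:
        dx, dy = spec.warp(trace.x, trace.y)
        x = x + dx
        y = y + dy
    if spec.precision_sd > 0:
        x = x + rng.normal(0.0, spec.precision_sd, size=x.shape)
        y = y + rng.normal(0.0, spec.precision_sd, size=y.shape)
    return EyeTrace(trace.t.copy(), x, y, trace.rate, trace.valid.copy())
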