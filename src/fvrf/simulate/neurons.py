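"""Model neurons: linear-nonlinear-Poisson (LNP) simple cells, energy-model
complex cells, grating-tuned units and motion (MT-like) units.

Every unit's receptive field is anchored at a RETINAL position: on each frame
the stimulus is shifted by minus the (true) gaze before the filter is applied,
so the unit "moves with the gaze".  Spiking is Poisson at frame resolution.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..datatypes import (
    DotStimulus,
    EyeTrace,
    GratingStimulus,
    MotionDotStimulus,
    SpikeTrain,
)

__all__ = [
    "NeuronModel",
    "simulate_neuron",
    "simulate_pixel_neuron",
    "default_temporal_kernel",
    "filter_image",
]


def default_temporal_kernel(n_lags: int = 6, peak_lag: int = 2) -> np.ndarray:
    """Biphasic temporal kernel, peak-normalized to 1 at ``peak_lag``."""
    lags = np.arange(n_lags, dtype=float)
    k = np.exp(-0.5 * ((lags - peak_lag) / 0.9) ** 2) - 0.45 * np.exp(
        -0.5 * ((lags - peak_lag - 2.0) / 1.1) ** 2
    )
    k[0] = 0.0
    return k / np.max(np.abs(k))


@dataclass
class NeuronModel:
    """Parametric model neuron.

    kind : 'simple' | 'complex' | 'tuned' | 'mt'
    center : retinal anchor (x, y), d.v.a.
    baseline : spontaneous rate, spikes/s
    gain : drive-to-rate scale (simple/complex/mt)

    Simple/complex cells carry a Gabor spatial filter (``sigma``, carrier
    ``sf`` in cyc/d.v.a — 0 gives a Gaussian blob — orientation ``ori`` and
    ``phase``).  ``rectify_polarity`` makes the unit respond to absolute dot
    contrast (phase-invariant), which matches sign-ignored retinotopic
    binning.  Tuned units follow a separable orientation x spatial-frequency
    tuning surface with preferred (``pref_ori``, ``pref_sf``), concentration
    ``kappa`` and log-SF dispersion ``sf_sigma``, reaching ``max_rate`` at the
    preferred grating.  MT units weight each moving dot by a von Mises in
    direction (``pref_dir``, ``dir_kappa``) inside a Gaussian spatial envelope
    (``envelope_sigma``).
    """

    kind: str
    center: tuple[float, float] = (0.0, 0.0)
    baseline: float = 2.0
    gain: float = 1.0
    # simple / complex
    sigma: float = 0.5
    sf: float = 0.0
    ori: float = 0.0
    phase: float = 0.0
    rectify_polarity: bool = False
    # tuned
    pref_ori: float = 0.0
    pref_sf: float = 4.0
    kappa: float = 2.0
    sf_sigma: float = 0.35
    max_rate: float = 40.0
    # mt
    pref_dir: float = 0.0
    dir_kappa: float = 1.5
    envelope_sigma: float = 1.5
    temporal_kernel: np.ndarray = field(default_factory=default_temporal_kernel)

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.gain < 0 or self.max_rate < 0:
            raise ValueError("rates must be nonnegative")
        if not np.all(np.isfinite(self.temporal_kernel)):
            raise ValueError("temporal kernel must be finite")

    # ---- spatial filter ---------------------------------------------------
    def filter_value(self, dx: np.ndarray, dy: np.ndarray, quadrature: bool = False):
        """Gabor (or Gaussian, sf=0) filter evaluated at retinal offsets."""
        env = np.exp(-(dx**2 + dy**2) / (2.0 * self.sigma**2))
        if self.sf == 0.0:
            return env
        u = dx * np.cos(self.ori) + dy * np.sin(self.ori)
        ph = self.phase + (np.pi / 2 if quadrature else 0.0)
        return env * np.cos(2 * np.pi * self.sf * u + ph)


def _temporal_filter(drive: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = np.convolve(drive, kernel)[: drive.size]
    return out


def _orientation_factor(theta, pref, kappa):
    return (np.exp(kappa * np.cos(theta - pref) ** 2) - 1.0) / (np.exp(kappa) - 1.0)


def _sf_factor(omega, pref, sigma):
    return np.exp(-((np.log1p(omega) - np.log1p(pref)) ** 2) / (2.0 * sigma**2))


def _poissonize(rate: np.ndarray, frame_times: np.ndarray, frame_rate: float, rng):
    counts = rng.poisson(np.clip(rate, 0.0, None) / frame_rate)
    times = np.repeat(frame_times, counts) + rng.uniform(
        0.0, 1.0 / frame_rate, size=int(counts.sum())
    )
    return counts.astype(float), np.sort(times)


def simulate_neuron(
    model: NeuronModel,
    stimulus,
    true_trace: EyeTrace,
    seed: int | None = 0,
    unit: int = 0,
) -> tuple[SpikeTrain, np.ndarray, np.ndarray]:
    """Simulate Poisson spiking of ``model`` driven by ``stimulus`` viewed
    through the TRUE eye trace.

    Returns (SpikeTrain, per-frame counts, per-frame rate in spikes/s).
    """
    rng = np.random.default_rng(seed)
    ft = stimulus.frame_times
    frame_rate = stimulus.frame_rate
    gx, gy = true_trace.position_at(ft)
    k = model.temporal_kernel

    if isinstance(stimulus, DotStimulus):
        dx = stimulus.x - gx[:, None] - model.center[0]
        dy = stimulus.y - gy[:, None] - model.center[1]
        pol = np.abs(stimulus.polarity) if model.rectify_polarity else stimulus.polarity
        if model.kind == "simple":
            d = _temporal_filter((pol * model.filter_value(dx, dy)).sum(axis=1), k)
            rate = model.baseline + model.gain * np.clip(d, 0.0, None) ** 2
        elif model.kind == "complex":
            d1 = _temporal_filter((pol * model.filter_value(dx, dy)).sum(axis=1), k)
            d2 = _temporal_filter(
                (pol * model.filter_value(dx, dy, quadrature=True)).sum(axis=1), k
            )
            rate = model.baseline + model.gain * (d1**2 + d2**2)
        else:
            raise ValueError(f"kind {model.kind!r} incompatible with dot stimulus")
    elif isinstance(stimulus, GratingStimulus):
        if model.kind != "tuned":
            raise ValueError("grating stimulus drives 'tuned' units")
        drive = np.zeros(ft.size)
        ok = ~stimulus.blank
        drive[ok] = (
            (stimulus.contrast / 0.25)
            * _orientation_factor(stimulus.orientation[ok], model.pref_ori, model.kappa)
            * _sf_factor(stimulus.spatial_freq[ok], model.pref_sf, model.sf_sigma)
        )
        d = _temporal_filter(drive, k)
        rate = model.baseline + (model.max_rate - model.baseline) * np.clip(d, 0.0, None)
    elif isinstance(stimulus, MotionDotStimulus):
        if model.kind != "mt":
            raise ValueError("motion-dot stimulus drives 'mt' units")
        moved = stimulus.age > 0  # replotted dots carry no motion signal
        ddx = stimulus.x - gx[:, None] - model.center[0]
        ddy = stimulus.y - gy[:, None] - model.center[1]
        env = np.exp(-(ddx**2 + ddy**2) / (2.0 * model.envelope_sigma**2))
        theta = stimulus.directions[stimulus.dir_idx]
        w = np.exp(model.dir_kappa * (np.cos(theta - model.pref_dir) - 1.0))
        d = _temporal_filter((moved * env * w).sum(axis=1), k)
        rate = model.baseline + model.gain * np.clip(d, 0.0, None)
    else:
        raise TypeError(f"unsupported stimulus type {type(stimulus)!r}")

    counts, times = _poissonize(rate, ft, frame_rate, rng)
    return SpikeTrain(unit=unit, times=times), counts, rate


# ---------------------------------------------------------------------------
# pixel-movie neurons (high-resolution ROI analyses)
# ---------------------------------------------------------------------------

def filter_image(
    model: NeuronModel, shape: tuple[int, int], pitch: float,
    center_px: tuple[float, float] | None = None,
) -> np.ndarray:
    """Render the unit's spatial filter on a pixel grid.

    ``pitch`` is d.v.a per pixel; row 0 is the TOP of the ROI (+y up means
    decreasing row index).  ``center_px`` overrides the model's d.v.a center
    with an explicit (row, col) position.
    """
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    if center_px is None:
        c_col = (w - 1) / 2 + model.center[0] / pitch
        c_row = (h - 1) / 2 - model.center[1] / pitch
    else:
        c_row, c_col = center_px
    dx = (cols - c_col) * pitch
    dy = (c_row - rows) * pitch
    return model.filter_value(dx, dy)


def simulate_pixel_neuron(
    model: NeuronModel,
    movie: np.ndarray,
    frame_rate: float,
    pitch: float,
    seed: int | None = 0,
    unit: int = 0,
    center_px: tuple[float, float] | None = None,
) -> tuple[SpikeTrain, np.ndarray, np.ndarray, np.ndarray]:
    """Drive an LNP unit with a retinal (already gaze-aligned) pixel movie.

    movie : (T, h, w) luminance relative to mean gray.
    Returns (SpikeTrain, counts, rate, filter image).
    """
    rng = np.random.default_rng(seed)
    f = filter_image(model, movie.shape[1:], pitch, center_px)
    k = model.temporal_kernel
    drive = np.tensordot(movie, f, axes=([1, 2], [0, 1]))
    if model.kind == "simple":
        d = _temporal_filter(drive, k)
        rate = model.baseline + model.gain * np.clip(d, 0.0, None) ** 2
    elif model.kind == "complex":
        f2 = filter_image(
            NeuronModel(**{**model.__dict__, "phase": model.phase + np.pi / 2}),
            movie.shape[1:], pitch, center_px,
        )
        d1 = _temporal_filter(drive, k)
        d2 = _temporal_filter(
            np.tensordot(movie, f2, axes=([1, 2], [0, 1])), k
        )
        rate = model.baseline + model.gain * (d1**2 + d2**2)
    else:
        raise ValueError("pixel-movie simulation supports simple/complex units")
    ft = np.arange(movie.shape[0]) / frame_rate
    counts, times = _poissonize(rate, ft, frame_rate, rng)
    return SpikeTrain(unit=unit, times=times), counts, rate, f
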