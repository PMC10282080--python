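"""Core data containers shared across the package.

Coordinate convention: screen-centered degrees of visual angle (d.v.a.),
+x rightward, +y upward.  Pixel-space conversions (y down) are confined to
rendering and I/O code.  Times are in seconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
import json

import numpy as np
import pandas as pd

__all__ = [
    "EyeTrace",
    "DotStimulus",
    "GratingStimulus",
    "MotionDotStimulus",
    "SpikeTrain",
    "TrackerNoiseSpec",
    "bin_spikes",
]


@dataclass
class EyeTrace:
    """Uniformly sampled gaze position.

    Parameters
    ----------
    t : array, seconds, strictly increasing at 1/rate
    x, y : array, d.v.a., screen-centered
    rate : sampling rate in Hz
    valid : boolean array; invalid samples (blinks, tracking dropouts) are
        excluded from kinematic computations.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rate: float
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.t.shape == self.x.shape == self.y.shape == self.valid.shape):
            raise ValueError("t, x, y, valid must have matching shapes")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0

    def position_at(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gaze position at arbitrary times by nearest-sample lookup."""
        times = np.asarray(times, dtype=float)
        idx = np.clip(
            np.round((times - self.t[0]) * self.rate).astype(int), 0, len(self) - 1
        )
        return self.x[idx], self.y[idx]

    def copy(self) -> "EyeTrace":
        return EyeTrace(
            self.t.copy(), self.x.copy(), self.y.copy(), self.rate, self.valid.copy()
        )

    # ---- I/O -------------------------------------------------------------
    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"t": self.t, "x": self.x, "y": self.y, "valid": self.valid.astype(int)}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EyeTrace":
        df = pd.read_csv(path)
        t = df["t"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        valid = df["valid"].to_numpy().astype(bool) if "valid" in df else None
        return cls(t, df["x"].to_numpy(), df["y"].to_numpy(), rate, valid)


@dataclass
class TrackerNoiseSpec:
    """Eye-tracker error model: additive precision noise plus a multiplicative
    calibration gain about screen center, with an optional smooth warp field.

    precision_sd : per-sample Gaussian noise SD, d.v.a.
    gain : unitless gain applied about the screen center (calibration error).
    warp : optional callable (x, y) -> (dx, dy) added to the reported gaze,
        used to emulate smooth nonlinear miscalibration.
    """

    precision_sd: float = 0.0
    gain: float = 1.0
    warp: object | None = None

    def __post_init__(self) -> None:
        if self.precision_sd < 0:
            raise ValueError("precision_sd must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")


@dataclass
class DotStimulus:
    """Sparse-noise stimulus: flashed dots at random screen positions.

    Arrays are (n_frames, dots_per_frame); ``polarity`` is +1 (white) or -1
    (black) relative to mean gray.
    """

    frame_times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    polarity: np.ndarray
    dot_size: float
    frame_rate: float
    screen: tuple[float, float]  # (width, height) in d.v.a.
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def dots_per_frame(self) -> int:
        return self.x.shape[1]

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            header = {
                "kind": "dots",
                "dot_size": self.dot_size,
                "frame_rate": self.frame_rate,
                "screen": list(self.screen),
                "seed": self.seed,
            }
            fh.write(json.dumps(header) + "\n")
            for i in range(self.n_frames):
                rec = {
                    "frame": i,
                    "t": float(self.frame_times[i]),
                    "x": self.x[i].tolist(),
                    "y": self.y[i].tolist(),
                    "pol": self.polarity[i].astype(int).tolist(),
                }
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "DotStimulus":
        with open(path) as fh:
            header = json.loads(fh.readline())
            frames = [json.loads(line) for line in fh if line.strip()]
        return cls(
            frame_times=np.array([r["t"] for r in frames]),
            x=np.array([r["x"] for r in frames]),
            y=np.array([r["y"] for r in frames]),
            polarity=np.array([r["pol"] for r in frames], dtype=float),
            dot_size=header["dot_size"],
            frame_rate=header["frame_rate"],
            screen=tuple(header["screen"]),
            seed=header["seed"],
        )


@dataclass
class GratingStimulus:
    """Full-field flashed gratings: one (orientation, spatial frequency,
    phase) triple per frame, or a blank gray frame."""

    frame_times: np.ndarray
    orientation: np.ndarray  # radians in [0, pi)
    spatial_freq: np.ndarray  # cycles / d.v.a.
    phase: np.ndarray  # radians
    blank: np.ndarray  # bool
    contrast: float
    frame_rate: float
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.frame_times.size


@dataclass
class MotionDotStimulus:
    """Sparse motion noise: dots drifting at fixed speed in one of ``n_dirs``
    directions, replotted at a random position when their lifetime expires.

    ``age`` counts frames since (re)plot: a dot with age 0 on frame t was
    replotted on frame t and contributed no displacement on the t-1 -> t
    transition.
    """

    frame_times: np.ndarray
    x: np.ndarray  # (n_frames, max_dots)
    y: np.ndarray
    dir_idx: np.ndarray  # (n_frames, max_dots) int
    age: np.ndarray  # (n_frames, max_dots) int
    directions: np.ndarray  # (n_dirs,) radians
    speed: float  # d.v.a / s
    lifetime: int  # frames
    dot_size: float
    frame_rate: float
    screen: tuple[float, float]
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def max_dots(self) -> int:
        return self.x.shape[1]


@dataclass
class SpikeTrain:
    """Spike times for one unit, with per-frame counts when binned."""

    unit: int
    times: np.ndarray

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def to_csv(self, path) -> None:
        pd.DataFrame({"unit": self.unit, "t": self.times}).to_csv(path, index=False)


def bin_spikes(times: np.ndarray, frame_times: np.ndarray, frame_rate: float) -> np.ndarray:
    """Count spikes in frame bins aligned to frame onsets.

    Bin t spans [frame_times[t], frame_times[t] + 1/frame_rate).
    """
    edges = np.append(frame_times, frame_times[-1] + 1.0 / frame_rate)
    counts, _ = np.histogram(times, bins=edges)
    return counts.astype(float)
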