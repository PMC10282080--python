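"""Synthetic eye-camera frames for the dual-Purkinje localization algorithm.

Each 8-bit frame contains a bright, large Gaussian blob (the first Purkinje
reflection, P1) and a dim, small blob (P4).  Eye rotation displaces the two
blobs by different linear gains, so the P1-P4 vector is linear in rotation —
the geometric property the tracker exploits.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OpticsSpec", "render_eye_camera_frames"]


@dataclass
class OpticsSpec:
    frame_shape: tuple[int, int] = (96, 128)  # (rows, cols)
    p1_ref: tuple[float, float] = (48.0, 40.0)  # (row, col) at zero rotation
    p4_ref: tuple[float, float] = (48.0, 90.0)
    p1_gain: float = 6.0  # px per d.v.a of rotation
    p4_gain: float = 2.0
    p1_sigma: float = 5.0
    p4_sigma: float = 1.6
    p1_peak: float = 255.0
    p4_peak: float = 90.0
    noise_sd: float = 0.0  # additive Gaussian, 8-bit counts

    @property
    def displacement_gain(self) -> float:
        """(P1 - P4) px per d.v.a of rotation."""
        return self.p1_gain - self.p4_gain


def _blob(rows, cols, center, sigma, peak):
    return peak * np.exp(
        -((rows - center[0]) ** 2 + (cols - center[1]) ** 2) / (2.0 * sigma**2)
    )


def render_eye_camera_frames(
    rotations: np.ndarray,
    optics: OpticsSpec | None = None,
    seed: int | None = 0,
) -> tuple[np.ndarray, dict]:
    """Render 8-bit frames for a sequence of eye rotations.

    rotations : (n, 2) array of (horizontal, vertical) rotation in d.v.a.
        Horizontal rotation moves the blobs along columns, vertical along
        rows (camera row axis points down, so +vertical decreases row).

    Returns (frames uint8 (n, H, W), ground truth dict with per-frame P1/P4
    centers in (row, col) pixels).
    """
    optics = optics or OpticsSpec()
    rng = np.random.default_rng(seed)
    rotations = np.atleast_2d(np.asarray(rotations, dtype=float))
    n = rotations.shape[0]
    h, w = optics.frame_shape
    rows, cols = np.mgrid[0:h, 0:w]
    frames = np.empty((n, h, w), dtype=np.uint8)
    p1_centers = np.empty((n, 2))
    p4_centers = np.empty((n, 2))
    for i, (rx, ry) in enumerate(rotations):
        p1 = (optics.p1_ref[0] - optics.p1_gain * ry, optics.p1_ref[1] + optics.p1_gain * rx)
        p4 = (optics.p4_ref[0] - optics.p4_gain * ry, optics.p4_ref[1] + optics.p4_gain * rx)
        img = _blob(rows, cols, p1, optics.p1_sigma, optics.p1_peak)
        img += _blob(rows, cols, p4, optics.p4_sigma, optics.p4_peak)
        if optics.noise_sd > 0:
            img += rng.normal(0.0, optics.noise_sd, size=img.shape)
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)
        p1_centers[i] = p1
        p4_centers[i] = p4
    return frames, {"p1": p1_centers, "p4": p4_centers, "optics": optics}
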