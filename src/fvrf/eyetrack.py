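"""Eye tracking: dual-Purkinje localization on camera frames, offline
bilinear calibration refinement, and saccade detection from eye kinematics.

Saccade detection follows the classic velocity/acceleration recipe: the gaze
signal is resampled at 1 kHz, differentiated with a local-polynomial
(Savitzky-Golay) filter, candidates are taken at negative-going zero
crossings of the acceleration (local maxima of speed), retained when peak
speed exceeds 8 deg/s and peak acceleration 2000 deg/s^2 within a 150 ms
window, and delimited by the surrounding 10 deg/s speed crossings.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d
from scipy.ndimage import uniform_filter
from scipy.signal import savgol_filter
from skimage.feature import match_template
from skimage.measure import block_reduce

from .datatypes import EyeTrace

__all__ = [
    "SaccadeEvent",
    "CalibrationParams",
    "PurkinjeTrack",
    "track_purkinje",
    "p4_template",
    "refine_calibration_bilinear",
    "detect_saccades",
    "analysis_mask",
]

VELOCITY_THRESHOLD = 8.0  # deg/s, candidate retention
ACCEL_THRESHOLD = 2000.0  # deg/s^2
ONOFF_THRESHOLD = 10.0  # deg/s, start/end crossing
CANDIDATE_WINDOW = 0.150  # s, examination window around each candidate


@dataclass
class SaccadeEvent:
    t_start: float
    t_end: float
    t_peak: float
    peak_velocity: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_peak < self.t_end):
            raise ValueError("require t_start < t_peak < t_end")


@dataclass
class CalibrationParams:
    """Per-axis affine map from raw tracker output to calibrated gaze:
    calibrated = offset + gain * raw."""

    offset_x: float
    offset_y: float
    gain_x: float
    gain_y: float
    n_pairs: int = 0

    def __post_init__(self) -> None:
        if self.gain_x <= 0 or self.gain_y <= 0:
            raise ValueError("gains must be > 0")

    def apply(self, x, y):
        return self.offset_x + self.gain_x * np.asarray(x), (
            self.offset_y + self.gain_y * np.asarray(y)
        )

    @property
    def implied_tracker_gain(self) -> tuple[float, float]:
        """If raw = g*true + o, the fitted map is the inverse; recover g."""
        return 1.0 / self.gain_x, 1.0 / self.gain_y

    @property
    def implied_tracker_offset(self) -> tuple[float, float]:
        return -self.offset_x / self.gain_x, -self.offset_y / self.gain_y


# ---------------------------------------------------------------------------
# dual-Purkinje localization
# ---------------------------------------------------------------------------

@dataclass
class PurkinjeTrack:
    p1: np.ndarray  # (n, 2) full-resolution (row, col) centers
    p4: np.ndarray
    displacement: np.ndarray  # (n, 2) P1-P4 in screen-style (x right, y up) px
    valid: np.ndarray


def p4_template(sigma: float = 1.6, peak: float = 90.0, radius: int = 4,
                downsample: int = 4) -> np.ndarray:
    """Ideal P4 matching template on the downsampled grid."""
    r = radius
    rows, cols = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    s = sigma / downsample
    return peak * np.exp(-(rows**2 + cols**2) / (2.0 * max(s, 0.5) ** 2))


def _iterated_centroid(img: np.ndarray, start: np.ndarray, radius: int,
                       n_iter: int = 3) -> np.ndarray:
    """Intensity centroid in a square window, re-centered a few times."""
    c = np.asarray(start, dtype=float)
    h, w = img.shape
    for _ in range(n_iter):
        r0 = int(np.clip(round(c[0]) - radius, 0, h - 1))
        r1 = int(np.clip(round(c[0]) + radius + 1, 1, h))
        c0 = int(np.clip(round(c[1]) - radius, 0, w - 1))
        c1 = int(np.clip(round(c[1]) + radius + 1, 1, w))
        win = img[r0:r1, c0:c1].astype(float)
        tot = win.sum()
        if tot <= 0:
            return c
        rows, cols = np.mgrid[r0:r1, c0:c1]
        c = np.array([(win * rows).sum() / tot, (win * cols).sum() / tot])
    return c


def radial_symmetry_center(img: np.ndarray) -> tuple[float, float]:
    """Gradient-based radial-symmetry center of a blob image.

    Estimates the point of maximal radial symmetry as the weighted
    least-squares intersection of the image-gradient lines (the standard
    particle-localization estimator); returns (row, col) in image
    coordinates.
    """
    I = img.astype(float)
    ny, nx = I.shape
    xm, ym = np.meshgrid(
        np.arange(nx - 1) + 0.5, np.arange(ny - 1) + 0.5
    )
    # Roberts-cross gradients on the 45-degree rotated lattice
    dIdu = I[:-1, 1:] - I[1:, :-1]
    dIdv = I[:-1, :-1] - I[1:, 1:]
    fdu = uniform_filter(dIdu, 3)
    fdv = uniform_filter(dIdv, 3)
    mag2 = fdu**2 + fdv**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = -(fdv + fdu) / (fdu - fdv)  # d(row)/d(col) of gradient line
    slope = np.where(np.isfinite(slope), slope, 0.0)
    intercept = ym - slope * xm
    tot = mag2.sum()
    if tot <= 0:
        return (ny - 1) / 2.0, (nx - 1) / 2.0
    xc0 = (mag2 * xm).sum() / tot
    yc0 = (mag2 * ym).sum() / tot
    dist = np.sqrt((xm - xc0) ** 2 + (ym - yc0) ** 2) + 1e-9
    w = mag2 / dist / (slope**2 + 1.0)
    sw = w.sum()
    smw = (slope * w).sum()
    smmw = (slope**2 * w).sum()
    sbw = (intercept * w).sum()
    smbw = (slope * intercept * w).sum()
    det = smw**2 - smmw * sw
    if abs(det) < 1e-12:
        return yc0, xc0
    xc = (smbw * sw - smw * sbw) / det
    yc = (smbw * smw - smmw * sbw) / det
    return yc, xc


def track_purkinje(
    frames: np.ndarray,
    template: np.ndarray | None = None,
    threshold: float = 200.0,
    downsample: int = 4,
    corr_floor: float = 0.4,
    p1_radius: int = 12,
    p4_radius: int = 6,
    p1_suppress_ds: float = 5.0,
    p4_method: str = "radial",
) -> PurkinjeTrack:
    """Two-stage P1/P4 localization.

    Stage 1 (coarse, on the x``downsample`` block-averaged frame): the P1
    region is the center of mass of pixels exceeding ``threshold`` (8-bit);
    the P4 region is the peak of the normalized cross-correlation with
    ``template`` (P1's neighborhood excluded).  Stage 2 refines within
    full-resolution windows: intensity centroid for P1, radial-symmetry
    center for P4 (``p4_method='centroid'`` falls back to the centroid).

    Frames with no suprathreshold pixel (blinks) or a correlation peak below
    ``corr_floor`` are flagged invalid.
    """
    frames = np.atleast_3d(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if template is None:
        template = p4_template(downsample=downsample)
    n = frames.shape[0]
    p1 = np.full((n, 2), np.nan)
    p4 = np.full((n, 2), np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        img = frames[i].astype(float)
        ds = block_reduce(img, (downsample, downsample), np.mean)
        mask = ds > threshold
        if not mask.any():
            continue  # blink: no P1
        wsum = (ds * mask).sum()
        rows, cols = np.mgrid[0 : ds.shape[0], 0 : ds.shape[1]]
        p1_ds = np.array(
            [(ds * mask * rows).sum() / wsum, (ds * mask * cols).sum() / wsum]
        )
        # template-match on the raw frame, but exclude P1's neighborhood
        # from the correlation map so the bright blob cannot win
        cc = match_template(ds, template, pad_input=True)
        rr = (rows - p1_ds[0]) ** 2 + (cols - p1_ds[1]) ** 2
        cc[rr < p1_suppress_ds**2] = -1.0
        peak = np.unravel_index(np.argmax(cc), cc.shape)
        if cc[peak] < corr_floor:
            continue
        p1_full = _iterated_centroid(img, p1_ds * downsample, p1_radius)
        p4_start = np.array(peak, dtype=float) * downsample
        p4_c = _iterated_centroid(img, p4_start, p4_radius)
        if p4_method == "radial":
            r0 = int(np.clip(round(p4_c[0]) - p4_radius, 0, img.shape[0] - 1))
            c0 = int(np.clip(round(p4_c[1]) - p4_radius, 0, img.shape[1] - 1))
            win = img[r0 : r0 + 2 * p4_radius + 1, c0 : c0 + 2 * p4_radius + 1]
            rr_, cc_ = radial_symmetry_center(win)
            p4_c = np.array([r0 + rr_, c0 + cc_])
        p1[i] = p1_full
        p4[i] = p4_c
        valid[i] = True
    disp = np.column_stack(
        [p1[:, 1] - p4[:, 1], -(p1[:, 0] - p4[:, 0])]  # x right, y up
    )
    return PurkinjeTrack(p1=p1, p4=p4, displacement=disp, valid=valid)


# ---------------------------------------------------------------------------
# calibration refinement
# ---------------------------------------------------------------------------

def refine_calibration_bilinear(
    fixations: np.ndarray,
    targets: np.ndarray,
    match_radius: float = 1.0,
) -> CalibrationParams:
    """Offline calibration refinement against fixation targets.

    Each fixation mean position is matched to the nearest grid target; pairs
    farther than ``match_radius`` (1 d.v.a) are dropped.  A per-axis affine
    (offset + gain) map from raw fixation position to target position is then
    fit by least squares.

    Parameters
    ----------
    fixations : (n, 2) mean raw gaze position during each detected fixation
    targets : (m, 2) calibration-grid target positions
    """
    fixations = np.atleast_2d(np.asarray(fixations, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    d2 = ((fixations[:, None, :] - targets[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(len(fixations)), nearest])
    keep = dist <= match_radius
    if keep.sum() < 3:
        raise ValueError(
            f"need >= 3 fixation-target matches within {match_radius} d.v.a, "
            f"got {int(keep.sum())}"
        )
    fx = fixations[keep]
    tg = targets[nearest[keep]]
    if np.linalg.matrix_rank(np.column_stack([fx, np.ones(len(fx))])) < 3:
        raise ValueError("matched fixation-target pairs are collinear")
    params = []
    for axis in range(2):
        A = np.column_stack([np.ones(keep.sum()), fx[:, axis]])
        coef, *_ = np.linalg.lstsq(A, tg[:, axis], rcond=None)
        params.append(coef)
    return CalibrationParams(
        offset_x=params[0][0],
        offset_y=params[1][0],
        gain_x=params[0][1],
        gain_y=params[1][1],
        n_pairs=int(keep.sum()),
    )


# ---------------------------------------------------------------------------
# saccade detection
# ---------------------------------------------------------------------------

def _resample_1khz(trace: EyeTrace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.arange(trace.t[0], trace.t[-1] + 0.5e-3, 1e-3)
    ok = trace.valid
    if ok.sum() < 2:
        return t, np.zeros_like(t), np.zeros_like(t)
    fx = interp1d(trace.t[ok], trace.x[ok], bounds_error=False,
                  fill_value=(trace.x[ok][0], trace.x[ok][-1]))
    fy = interp1d(trace.t[ok], trace.y[ok], bounds_error=False,
                  fill_value=(trace.y[ok][0], trace.y[ok][-1]))
    return t, fx(t), fy(t)


def detect_saccades(
    trace: EyeTrace,
    sg_window_ms: float = 11.0,
    sg_order: int = 3,
    merge_ms: float = 20.0,
) -> list[SaccadeEvent]:
    """Detect saccades with velocity/acceleration thresholds.

    The differentiating filter is a Savitzky-Golay local-polynomial
    derivative over ``sg_window_ms``; candidates closer than ``merge_ms`` are
    merged keeping the larger velocity peak.
    """
    if trace.duration < CANDIDATE_WINDOW:
        return []
    t, x, y = _resample_1khz(trace)
    win = int(round(sg_window_ms))
    win += 1 - win % 2  # odd
    if len(t) <= win:
        return []
    vx = savgol_filter(x, win, sg_order, deriv=1, delta=1e-3)
    vy = savgol_filter(y, win, sg_order, deriv=1, delta=1e-3)
    speed = np.hypot(vx, vy)
    accel = savgol_filter(speed, win, sg_order, deriv=1, delta=1e-3)

    # negative-going zero crossings of acceleration = local speed maxima
    cand = np.nonzero((accel[:-1] > 0) & (accel[1:] <= 0))[0]
    if cand.size == 0:
        return []
    # merge near-coincident candidates, keep the larger speed peak
    merged: list[int] = []
    for c in cand:
        if merged and (c - merged[-1]) < merge_ms:
            if speed[c] > speed[merged[-1]]:
                merged[-1] = c
        else:
            merged.append(c)

    half = int(CANDIDATE_WINDOW * 1000 / 2)
    events: list[SaccadeEvent] = []
    used_peaks: set[int] = set()
    for c in merged:
        lo = max(c - half, 0)
        hi = min(c + half + 1, len(speed))
        if speed[lo:hi].max() <= VELOCITY_THRESHOLD:
            continue
        if np.abs(accel[lo:hi]).max() <= ACCEL_THRESHOLD:
            continue
        peak = lo + int(np.argmax(speed[lo:hi]))
        if peak in used_peaks:
            continue
        # walk out to the 10 deg/s crossings around the peak
        i0 = peak
        while i0 > 0 and speed[i0] > ONOFF_THRESHOLD:
            i0 -= 1
        i1 = peak
        while i1 < len(speed) - 1 and speed[i1] > ONOFF_THRESHOLD:
            i1 += 1
        if i0 == peak or i1 == peak:
            continue
        # a candidate whose walk-out lands on an already-claimed saccade
        # (e.g. drift blips riding the saccade tail) is a duplicate
        if any(e.t_start <= t[i1] and t[i0] <= e.t_end for e in events):
            continue
        used_peaks.add(peak)
        amp = float(np.hypot(x[i1] - x[i0], y[i1] - y[i0]))
        events.append(
            SaccadeEvent(
                t_start=float(t[i0]),
                t_end=float(t[i1]),
                t_peak=float(t[peak]),
                peak_velocity=float(speed[peak]),
                amplitude=amp,
            )
        )
    return events


def analysis_mask(
    times: np.ndarray | EyeTrace,
    saccades: list[SaccadeEvent],
    post_saccade_exclusion_ms: float = 50.0,
) -> np.ndarray:
    """Boolean per-sample/per-frame mask: False during each saccade and for
    ``post_saccade_exclusion_ms`` after its end (post-saccadic lens wobble),
    True elsewhere."""
    if isinstance(times, EyeTrace):
        times = times.t
    times = np.asarray(times, dtype=float)
    mask = np.ones(times.shape, dtype=bool)
    pad = post_saccade_exclusion_ms / 1000.0
    for s in saccades:
        mask &= ~((times >= s.t_start) & (times <= s.t_end + pad))
    return mask
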