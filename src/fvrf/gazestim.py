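"""Gaze-contingent stimulus representations at three fidelities.

1. Coarse grid counts: each dot is assigned to the grid cell containing its
   RETINAL position (dot position minus gaze), giving a frames x cells count
   matrix — the design matrix of the retinotopic-mapping regression.
2. Velocity components: per-cell sums of horizontal/vertical dot velocities
   for motion-dot stimuli.
3. Full-resolution ROI movies: the stimulus re-rendered within a small
   gaze-anchored region of interest at arcminute pixel pitch.

Cells are half-open boxes [center - s/2, center + s/2) per axis, and dots are
assigned by their center point only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .datatypes import DotStimulus, EyeTrace, MotionDotStimulus

__all__ = [
    "Grid",
    "BinnedStimulus",
    "VelocityStimulus",
    "ROISpec",
    "ROIMovie",
    "bin_dots_gaze_contingent",
    "decompose_velocity",
    "reconstruct_roi_movie",
]


@dataclass
class Grid:
    """Regular rectangular grid in gaze-centered d.v.a. coordinates."""

    x_centers: np.ndarray
    y_centers: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        self.x_centers = np.asarray(self.x_centers, dtype=float)
        self.y_centers = np.asarray(self.y_centers, dtype=float)

    @classmethod
    def centered(cls, extent: tuple[float, float] = (28.0, 16.0),
                 spacing: float = 1.0) -> "Grid":
        """Grid of half-open cells tiling a gaze-centered extent.

        The default tiles 28 x 16 d.v.a at 1 d.v.a spacing (448 cells with
        centers on the half-integer lattice).
        """
        w, h = extent
        nx = int(round(w / spacing))
        ny = int(round(h / spacing))
        xc = (np.arange(nx) - (nx - 1) / 2) * spacing
        yc = (np.arange(ny) - (ny - 1) / 2) * spacing
        return cls(xc, yc, spacing)

    @classmethod
    def from_bbox(cls, x0, x1, y0, y1, n_bins: int = 20) -> "Grid":
        """n_bins x n_bins grid spanning a bounding box (fine stage)."""
        sx = (x1 - x0) / n_bins
        sy = (y1 - y0) / n_bins
        s = max(sx, sy)  # square cells spanning the larger side
        xc = x0 + (np.arange(n_bins) + 0.5) * sx
        yc = y0 + (np.arange(n_bins) + 0.5) * sy
        g = cls(xc, yc, sx)
        g.spacing_y = sy
        return g

    @property
    def nx(self) -> int:
        return self.x_centers.size

    @property
    def ny(self) -> int:
        return self.y_centers.size

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def spacing_x(self) -> float:
        return float(self.x_centers[1] - self.x_centers[0]) if self.nx > 1 else self.spacing

    def _spacing_y(self) -> float:
        if hasattr(self, "spacing_y"):
            return float(self.spacing_y)
        return float(self.y_centers[1] - self.y_centers[0]) if self.ny > 1 else self.spacing

    def assign(self, x: np.ndarray, y: np.ndarray):
        """Half-open cell assignment; returns (flat index, in-extent mask).

        Flat index = iy * nx + ix (row-major over y).
        """
        sx = self.spacing_x
        sy = self._spacing_y()
        ix = np.floor((x - (self.x_centers[0] - sx / 2)) / sx).astype(int)
        iy = np.floor((y - (self.y_centers[0] - sy / 2)) / sy).astype(int)
        ok = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        flat = np.where(ok, iy * self.nx + ix, -1)
        return flat, ok

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat arrays of per-cell (x, y) centers in assignment order."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        return xx.ravel(), yy.ravel()


@dataclass
class BinnedStimulus:
    """Gaze-contingent grid-resampled stimulus: sparse frames x cells."""

    X: sp.csr_matrix
    frame_times: np.ndarray
    grid: Grid
    frame_rate: float
    ignore_sign: bool = True
    n_dropped: int = 0

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]


@dataclass
class VelocityStimulus:
    """Per-cell horizontal/vertical velocity sums (d.v.a/s), sparse."""

    Vx: sp.csr_matrix
    Vy: sp.csr_matrix
    frame_times: np.ndarray
    grid: Grid
    frame_rate: float


def bin_dots_gaze_contingent(
    dots: DotStimulus,
    trace: EyeTrace,
    grid: Grid | None = None,
    ignore_sign: bool = True,
) -> BinnedStimulus:
    """Resample a dot stimulus onto a gaze-contingent grid.

    Per frame t each dot's retinal position (dot minus gaze) is assigned to
    the half-open cell containing its center; X(t) is the per-cell count
    (sign-ignored by default) or signed polarity sum.
    Frames outside the trace's time span are dropped (all-zero rows,
    counted in ``n_dropped``).
    """
    grid = grid or Grid.centered()
    ft = dots.frame_times
    covered = (ft >= trace.t[0]) & (ft <= trace.t[-1])
    gx, gy = trace.position_at(ft)
    rx = dots.x - gx[:, None]
    ry = dots.y - gy[:, None]
    flat, ok = grid.assign(rx, ry)
    ok = ok & covered[:, None]
    rows = np.broadcast_to(np.arange(dots.n_frames)[:, None], flat.shape)[ok]
    cols = flat[ok]
    vals = np.ones(ok.sum()) if ignore_sign else dots.polarity[ok]
    X = sp.coo_matrix(
        (vals, (rows, cols)), shape=(dots.n_frames, grid.n_cells)
    ).tocsr()
    return BinnedStimulus(
        X=X,
        frame_times=ft,
        grid=grid,
        frame_rate=dots.frame_rate,
        ignore_sign=ignore_sign,
        n_dropped=int((~covered).sum()),
    )


def decompose_velocity(
    motion: MotionDotStimulus,
    trace: EyeTrace,
    grid: Grid | None = None,
) -> VelocityStimulus:
    """Split each dot's frame-transition displacement into horizontal and
    vertical velocity components accumulated on a gaze-contingent grid.

    Dots replotted on a frame (age 0) contribute no displacement.  The
    default grid uses 2 d.v.a cells.
    """
    grid = grid or Grid.centered(spacing=2.0)
    ft = motion.frame_times
    gx, gy = trace.position_at(ft)
    rx = motion.x - gx[:, None]
    ry = motion.y - gy[:, None]
    flat, ok = grid.assign(rx, ry)
    moved = motion.age > 0
    ok = ok & moved
    theta = motion.directions[motion.dir_idx]
    vx = motion.speed * np.cos(theta)
    vy = motion.speed * np.sin(theta)
    rows = np.broadcast_to(np.arange(motion.n_frames)[:, None], flat.shape)[ok]
    cols = flat[ok]
    shape = (motion.n_frames, grid.n_cells)
    Vx = sp.coo_matrix((vx[ok], (rows, cols)), shape=shape).tocsr()
    Vy = sp.coo_matrix((vy[ok], (rows, cols)), shape=shape).tocsr()
    return VelocityStimulus(
        Vx=Vx, Vy=Vy, frame_times=ft, grid=grid, frame_rate=motion.frame_rate
    )


# ---------------------------------------------------------------------------
# full-resolution ROI movies
# ---------------------------------------------------------------------------

@dataclass
class ROISpec:
    """Gaze-anchored region of interest.

    shape : (h, w) pixels (default 70 x 70)
    pitch_arcmin : d.v.a per pixel * 60 (default 1.6 arcmin)
    anchor : ROI-center offset from gaze, d.v.a (retinotopic position)
    """

    shape: tuple[int, int] = (70, 70)
    pitch_arcmin: float = 1.6
    anchor: tuple[float, float] = (0.0, 0.0)

    @property
    def pitch(self) -> float:
        """d.v.a per pixel."""
        return self.pitch_arcmin / 60.0


@dataclass
class ROIMovie:
    movie: np.ndarray  # (T, h, w) luminance re: mean gray, float32
    frame_times: np.ndarray
    frame_rate: float
    roi: ROISpec
    clipped: np.ndarray = field(default=None)  # frames where ROI left screen

    @property
    def n_frames(self) -> int:
        return self.movie.shape[0]


def _roi_pixel_offsets(roi: ROISpec):
    """Pixel-center offsets from the ROI center, d.v.a (+y up, row 0 top)."""
    h, w = roi.shape
    px = (np.arange(w) - (w - 1) / 2) * roi.pitch
    py = ((h - 1) / 2 - np.arange(h)) * roi.pitch
    return px, py


def reconstruct_roi_movie(
    dots: DotStimulus,
    trace: EyeTrace,
    roi: ROISpec | None = None,
    calibration_grid=None,
) -> ROIMovie:
    """Re-render the dot stimulus inside a gaze-contingent ROI.

    Frames are regenerated from the stored stimulus events (the per-frame dot
    records replayed from the generator seed) and evaluated analytically at
    the ROI pixel centers: each dot is a Gaussian luminance profile of
    SD ``dot_size/2`` and amplitude = polarity.  This is equivalent to
    cropping a full-screen rendering with sub-pixel (bilinear-exact)
    alignment at the gaze position.  ``calibration_grid``, when given, must
    expose ``shift_at(x, y) -> (dx, dy)``; the shift is added to the gaze
    before extraction.  ROI regions beyond the screen are background gray
    (0) and the frame is flagged in ``clipped``.
    """
    roi = roi or ROISpec()
    gx, gy = trace.position_at(dots.frame_times)
    if calibration_grid is not None:
        dx, dy = calibration_grid.shift_at(gx, gy)
        gx = gx + dx
        gy = gy + dy
    px, py = _roi_pixel_offsets(roi)
    h, w = roi.shape
    sig = dots.dot_size / 2.0
    half_extent = max(px[-1], py[0]) + 3 * sig
    sw, sh = dots.screen
    movie = np.zeros((dots.n_frames, h, w), dtype=np.float32)
    clipped = np.zeros(dots.n_frames, dtype=bool)
    for tfr in range(dots.n_frames):
        cx = gx[tfr] + roi.anchor[0]
        cy = gy[tfr] + roi.anchor[1]
        clipped[tfr] = (
            abs(cx) + half_extent > sw / 2 or abs(cy) + half_extent > sh / 2
        )
        # dots whose profile reaches into the ROI
        ddx = dots.x[tfr] - cx
        ddy = dots.y[tfr] - cy
        near = (np.abs(ddx) < half_extent) & (np.abs(ddy) < half_extent)
        if not near.any():
            continue
        ex = np.exp(-((px[None, :] - ddx[near, None]) ** 2) / (2 * sig**2))
        ey = np.exp(-((py[None, :] - ddy[near, None]) ** 2) / (2 * sig**2))
        movie[tfr] = np.einsum("d,dy,dx->yx", dots.polarity[tfr][near], ey, ex)
    return ROIMovie(
        movie=movie,
        frame_times=dots.frame_times,
        frame_rate=dots.frame_rate,
        roi=roi,
        clipped=clipped,
    )
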