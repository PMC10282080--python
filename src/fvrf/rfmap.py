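"""Spatiotemporal receptive-field estimation by regularized regression.

The estimator solves the penalized normal equations

    K = (X'X + lambda * D)^-1 X'R

where X is the time-embedded gaze-contingent stimulus, R the mean-subtracted
spike counts binned at frame resolution, and D a graph-Laplacian roughness
penalty over the space x lag lattice (4-neighbor in space, 2-neighbor in
lag).  lambda is chosen by cross-validation on a contiguous held-out time
block.  Weights are in spikes/s per dot when R is scaled to rates.

The module follows the Model/Results convention: construct a
``ReceptiveFieldModel`` from a binned stimulus and spike counts, call
``fit()``, and inspect the returned ``ReceptiveFieldResults``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.optimize import least_squares
from skimage.measure import label, regionprops

from .datatypes import DotStimulus, EyeTrace
from .gazestim import BinnedStimulus, Grid, bin_dots_gaze_contingent

__all__ = [
    "time_embed",
    "path_laplacian",
    "lattice_laplacian",
    "ReceptiveFieldModel",
    "ReceptiveFieldResults",
    "GaussianRFFit",
    "fit_gaussian_rf",
    "coarse_to_fine",
    "select_unit",
]

DEFAULT_LAMBDA_GRID = np.logspace(-2, 5, 8)


def time_embed(X, n_lags: int):
    """Time-embed a frames x cells design: row t concatenates
    X(t), X(t-1), ..., X(t-n_lags+1); pre-session lags are zero-padded.
    Columns are ordered lag-major: all cells at lag 0, then lag 1, ...
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if sp.issparse(X):
        T, _ = X.shape
        blocks = []
        for lag in range(n_lags):
            if lag == 0:
                blocks.append(X)
            else:
                pad = sp.csr_matrix((lag, X.shape[1]))
                blocks.append(sp.vstack([pad, X[: T - lag]]))
        return sp.hstack(blocks).tocsr()
    X = np.asarray(X)
    T, n = X.shape
    out = np.zeros((T, n_lags * n), dtype=X.dtype)
    for lag in range(n_lags):
        out[lag:, lag * n : (lag + 1) * n] = X[: T - lag]
    return out


def path_laplacian(n: int, wrap: bool = False) -> sp.csr_matrix:
    """Combinatorial Laplacian (degree minus adjacency) of a path (or ring)."""
    if n == 1:
        return sp.csr_matrix((1, 1))
    A = sp.diags([np.ones(n - 1), np.ones(n - 1)], [1, -1], format="lil")
    if wrap and n > 2:
        A[0, n - 1] = 1
        A[n - 1, 0] = 1
    A = A.tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    return (sp.diags(deg) - A).tocsr()


def lattice_laplacian(
    ny: int, nx: int, n_lags: int, wrap_x: bool = False
) -> sp.csr_matrix:
    """Graph Laplacian over the (lag, y, x) lattice matching the embedded
    column order (lag-major, then flat cell index iy*nx+ix).

    Space uses 4-neighbor adjacency (optionally wrapping the x axis, for
    circular stimulus dimensions such as orientation); lags form a chain.
    """
    Lx = path_laplacian(nx, wrap=wrap_x)
    Ly = path_laplacian(ny)
    Lcell = sp.kron(Ly, sp.eye(nx)) + sp.kron(sp.eye(ny), Lx)
    Llag = path_laplacian(n_lags)
    n_cells = nx * ny
    D = sp.kron(Llag, sp.eye(n_cells)) + sp.kron(sp.eye(n_lags), Lcell)
    return D.tocsr()


@dataclass
class ReceptiveFieldResults:
    """Fitted spatiotemporal RF and its cross-validation diagnostics.

    ``params`` has shape (n_lags * n_cells, n_units); use ``kernel(unit)``
    for the (n_lags, ny, nx) view and ``spatial_map(unit)`` for the spatial
    slice at the peak lag.
    """

    model: "ReceptiveFieldModel"
    params: np.ndarray
    lambda_: np.ndarray  # per-unit selected penalty
    cv_r2: np.ndarray  # per-unit held-out variance explained
    lambda_grid: np.ndarray
    cv_r2_path: np.ndarray  # (n_lambda, n_units)

    @property
    def n_units(self) -> int:
        return self.params.shape[1]

    def kernel(self, unit: int = 0) -> np.ndarray:
        g = self.model.grid
        return self.params[:, unit].reshape(self.model.n_lags, g.ny, g.nx)

    def peak_lag(self, unit: int = 0) -> int:
        k = self.kernel(unit)
        return int(np.argmax(np.linalg.norm(k.reshape(k.shape[0], -1), axis=1)))

    def spatial_map(self, unit: int = 0, lag: int | None = None) -> np.ndarray:
        k = self.kernel(unit)
        return k[self.peak_lag(unit) if lag is None else lag]

    def predict(self, Xemb=None) -> np.ndarray:
        X = self.model.Xemb if Xemb is None else Xemb
        return np.asarray(X @ self.params) + self.model._mean[None, :]

    def summary(self) -> str:
        lines = [
            "Receptive-field regression (ridge + graph-Laplacian penalty)",
            f"  frames: {self.model.Xemb.shape[0]}, "
            f"features: {self.model.Xemb.shape[1]} "
            f"({self.model.n_lags} lags x {self.model.grid.n_cells} cells)",
            f"  lambda grid: {np.array2string(self.lambda_grid, precision=2)}",
            "  unit   lambda     cv R^2   peak lag",
        ]
        for u in range(self.n_units):
            lines.append(
                f"  {u:4d}  {self.lambda_[u]:8.2g}  {self.cv_r2[u]:8.4f}"
                f"   {self.peak_lag(u):5d}"
            )
        return "\n".join(lines)


class ReceptiveFieldModel:
    """Penalized linear regression of spike counts on the time-embedded
    gaze-contingent stimulus.

    Parameters
    ----------
    stim : BinnedStimulus (or a frames x cells array plus ``grid=``)
    counts : per-frame spike counts, (T,) or (T, n_units)
    n_lags : temporal embedding depth in frames
    wrap_x : treat the grid's x axis as circular (used for orientation)
    """

    def __init__(self, stim, counts, n_lags: int = 8, grid: Grid | None = None,
                 frame_rate: float | None = None, wrap_x: bool = False):
        if isinstance(stim, BinnedStimulus):
            X = stim.X
            self.grid = stim.grid
            self.frame_rate = stim.frame_rate
        else:
            X = stim
            if grid is None:
                raise ValueError("grid required for raw design input")
            self.grid = grid
            self.frame_rate = frame_rate or 1.0
        counts = np.asarray(counts, dtype=float)
        if counts.ndim == 1:
            counts = counts[:, None]
        if counts.shape[0] != X.shape[0]:
            raise ValueError("counts and stimulus must have equal frame counts")
        self.counts = counts
        self.n_lags = n_lags
        self.Xemb = time_embed(X, n_lags)
        self.D = lattice_laplacian(self.grid.ny, self.grid.nx, n_lags,
                                   wrap_x=wrap_x)

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _solve(XtX: np.ndarray, D: np.ndarray, Xty: np.ndarray, lam: float):
        try:
            c = cho_factor(XtX + lam * D, lower=True)
            return cho_solve(c, Xty)
        except LinAlgError:
            return None

    def fit(self, lambda_grid: np.ndarray | None = None,
            cv_frac: float = 0.2) -> ReceptiveFieldResults:
        """Fit at each penalty on the first (1 - cv_frac) time block, pick
        the per-unit penalty maximizing held-out variance explained, then
        refit on all frames at the chosen penalty."""
        lambda_grid = np.asarray(
            DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, float
        )
        if lambda_grid.size == 0 or np.any(lambda_grid < 0):
            raise ValueError("lambda_grid must be nonempty with values >= 0")
        T = self.Xemb.shape[0]
        n_tr = int(round(T * (1.0 - cv_frac)))
        Xtr, Xte = self.Xemb[:n_tr], self.Xemb[n_tr:]
        mean = self.counts[:n_tr].mean(axis=0)
        Rtr = self.counts[:n_tr] - mean
        Rte = self.counts[n_tr:] - mean

        Dd = self.D.toarray()
        XtX = np.asarray((Xtr.T @ Xtr).todense() if sp.issparse(Xtr)
                         else Xtr.T @ Xtr)
        XtR = np.asarray(Xtr.T @ Rtr)
        ss_tot = (Rte**2).sum(axis=0)
        ss_tot = np.where(ss_tot > 0, ss_tot, np.inf)

        n_units = self.counts.shape[1]
        r2_path = np.full((lambda_grid.size, n_units), -np.inf)
        for j, lam in enumerate(lambda_grid):
            K = self._solve(XtX, Dd, XtR, lam)
            if K is None:
                continue  # singular system; skip this penalty
            resid = Rte - np.asarray(Xte @ K)
            r2_path[j] = 1.0 - (resid**2).sum(axis=0) / ss_tot
        if not np.any(np.isfinite(r2_path)):
            raise LinAlgError("all penalties produced singular systems")
        best = np.argmax(r2_path, axis=0)

        # refit on all frames at each unit's selected penalty
        mean_all = self.counts.mean(axis=0)
        Rall = self.counts - mean_all
        XtX_all = np.asarray((self.Xemb.T @ self.Xemb).todense()
                             if sp.issparse(self.Xemb)
                             else self.Xemb.T @ self.Xemb)
        XtR_all = np.asarray(self.Xemb.T @ Rall)
        params = np.empty_like(XtR_all)
        for j in np.unique(best):
            units = np.nonzero(best == j)[0]
            K = self._solve(XtX_all, Dd, XtR_all[:, units], lambda_grid[j])
            if K is None:  # fall back to the smallest solvable penalty
                for lam in np.sort(lambda_grid[lambda_grid > lambda_grid[j]]):
                    K = self._solve(XtX_all, Dd, XtR_all[:, units], lam)
                    if K is not None:
                        break
            params[:, units] = K
        self._mean = mean_all
        return ReceptiveFieldResults(
            model=self,
            params=params,
            lambda_=lambda_grid[best],
            cv_r2=r2_path[best, np.arange(n_units)],
            lambda_grid=lambda_grid,
            cv_r2_path=r2_path,
        )


# ---------------------------------------------------------------------------
# coarse -> fine two-stage mapping
# ---------------------------------------------------------------------------

def _threshold_blob(spatial_map: np.ndarray, grid: Grid):
    """Largest 8-connected component of the map thresholded at 50% of max;
    returns (centroid_x, centroid_y, bbox) in d.v.a."""
    mask = spatial_map >= 0.5 * spatial_map.max()
    if not mask.any():
        raise ValueError("no suprathreshold cells at 50% of max")
    lab = label(mask, connectivity=2)
    props = regionprops(lab)
    largest = max(props, key=lambda p: p.area)
    r, c = largest.centroid  # (row=y index, col=x index)
    sy = grid._spacing_y()
    sx = grid.spacing_x
    cx = np.interp(c, np.arange(grid.nx), grid.x_centers)
    cy = np.interp(r, np.arange(grid.ny), grid.y_centers)
    r0, c0, r1, c1 = largest.bbox  # half-open
    x0 = grid.x_centers[c0] - sx / 2
    x1 = grid.x_centers[c1 - 1] + sx / 2
    y0 = grid.y_centers[r0] - sy / 2
    y1 = grid.y_centers[r1 - 1] + sy / 2
    return cx, cy, (x0, x1, y0, y1)


def coarse_to_fine(
    coarse: ReceptiveFieldResults,
    dots: DotStimulus,
    trace: EyeTrace,
    unit: int = 0,
    n_bins: int = 20,
    bbox_scale: float = 2.0,
    n_lags: int | None = None,
    lambda_grid: np.ndarray | None = None,
    min_peak_z: float = 3.0,
    ignore_sign: bool = True,
):
    """Second-stage RF estimation on a fine grid around the coarse blob.

    The coarse spatial map at the peak lag is thresholded at 50% of max, the
    largest connected component's centroid and bounding box are found, the
    box is scaled about the centroid and re-binned with ``n_bins`` per axis,
    and the regression is refit.

    Returns (fine ReceptiveFieldResults, fine Grid, blob centroid (x, y)).
    """
    smap = coarse.spatial_map(unit)
    z = (smap.max() - smap.mean()) / (smap.std() + 1e-12)
    if z < min_peak_z:
        raise ValueError(f"coarse RF peak z={z:.2f} below floor {min_peak_z}")
    cx, cy, (x0, x1, y0, y1) = _threshold_blob(smap, coarse.model.grid)
    hw = bbox_scale * max(x1 - x0, y1 - y0) / 2.0
    fine_grid = Grid.from_bbox(cx - hw, cx + hw, cy - hw, cy + hw, n_bins)
    binned = bin_dots_gaze_contingent(dots, trace, fine_grid,
                                      ignore_sign=ignore_sign)
    n_lags = n_lags or coarse.model.n_lags
    model = ReceptiveFieldModel(binned, coarse.model.counts[:, unit],
                                n_lags=n_lags)
    return model.fit(lambda_grid), fine_grid, (cx, cy)


# ---------------------------------------------------------------------------
# 2D Gaussian fit and unit selection
# ---------------------------------------------------------------------------

@dataclass
class GaussianRFFit:
    mean: tuple[float, float]
    cov: np.ndarray  # 2x2, d.v.a^2
    amplitude: float
    baseline: float
    r2: float
    s1: float = field(init=False)
    s2: float = field(init=False)
    area: float = field(init=False)

    def __post_init__(self) -> None:
        ev = np.linalg.eigvalsh(self.cov)
        if np.any(ev <= 0):
            raise ValueError("covariance must be positive definite")
        self.s1, self.s2 = np.sqrt(ev[::-1])
        self.area = float(np.pi * self.s1 * self.s2)


def _gauss_model(p, xx, yy):
    b, A, mx, my, l11, l21, l22 = p
    # Cholesky parameterization keeps the covariance positive definite
    Li = np.array([[l11, 0.0], [l21, l22]])
    cov = Li @ Li.T
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[0, 1], cov[0, 0]]]) / det
    dx = xx - mx
    dy = yy - my
    q = inv[0, 0] * dx**2 + 2 * inv[0, 1] * dx * dy + inv[1, 1] * dy**2
    return b + A * np.exp(-0.5 * q)


def fit_gaussian_rf(spatial_map: np.ndarray, grid: Grid,
                    n_starts: int = 5, seed: int = 0) -> GaussianRFFit:
    """Least-squares 2D Gaussian fit to the spatial slice at the peak lag,
    with a moment-based start plus ``n_starts`` seeded perturbations (best
    SSE wins).  Area is pi*s1*s2, the 1-SD ellipse area."""
    if spatial_map.shape[0] < 5 or spatial_map.shape[1] < 5:
        raise ValueError("need at least a 5x5 map")
    if not np.all(np.isfinite(spatial_map)):
        raise ValueError("map must be finite")
    xx, yy = np.meshgrid(grid.x_centers, grid.y_centers)
    z = spatial_map.astype(float)
    # moment-based initialization
    b0 = np.percentile(z, 10)
    w = np.clip(z - b0, 0, None)
    w = w / (w.sum() + 1e-12)
    mx0 = (w * xx).sum()
    my0 = (w * yy).sum()
    vx = max((w * (xx - mx0) ** 2).sum(), (grid.spacing_x / 2) ** 2)
    vy = max((w * (yy - my0) ** 2).sum(), (grid._spacing_y() / 2) ** 2)
    p0 = np.array([b0, z.max() - b0, mx0, my0, np.sqrt(vx), 0.0, np.sqrt(vy)])

    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts + 1):
        p_init = p0 if k == 0 else p0 * rng.normal(1.0, 0.2, size=p0.shape)
        p_init[4] = abs(p_init[4]) + 1e-3
        p_init[6] = abs(p_init[6]) + 1e-3
        try:
            res = least_squares(
                lambda p: (_gauss_model(p, xx, yy) - z).ravel(), p_init,
                method="lm", max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("Gaussian fit failed from all starts")
    p = best.x
    Li = np.array([[p[4], 0.0], [p[5], p[6]]])
    cov = Li @ Li.T
    pred = _gauss_model(p, xx, yy)
    ss_res = ((pred - z) ** 2).sum()
    ss_tot = ((z - z.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    # guard against numerically singular optimum: refit diagonally
    if np.linalg.det(cov) <= 1e-12:
        cov = np.diag(np.maximum(np.diag(cov), 1e-6))
    return GaussianRFFit(
        mean=(float(p[2]), float(p[3])), cov=cov,
        amplitude=float(p[1]), baseline=float(p[0]), r2=float(r2),
    )


def select_unit(
    results: ReceptiveFieldResults,
    gfit: GaussianRFFit,
    centroid: tuple[float, float] | None = None,
    unit: int = 0,
    r2_threshold: float = 0.4,
    max_center_shift: float = 0.25,
) -> tuple[bool, dict]:
    """Selection criteria: (a) the linear RF explains more held-out variance
    than the mean rate (cv R^2 > 0) and (b) the Gaussian fit has r^2 > 0.4.
    Units whose fitted mean shifted more than ``max_center_shift`` d.v.a from
    the thresholded-blob centroid are excluded."""
    crit_a = bool(results.cv_r2[unit] > 0.0)
    crit_b = bool(gfit.r2 > r2_threshold)
    shift_ok = True
    if centroid is not None:
        shift = float(np.hypot(gfit.mean[0] - centroid[0],
                               gfit.mean[1] - centroid[1]))
        shift_ok = shift <= max_center_shift
    report = {
        "cv_r2": float(results.cv_r2[unit]),
        "gaussian_r2": float(gfit.r2),
        "center": [float(gfit.mean[0]), float(gfit.mean[1])],
        "area": float(gfit.area),
        "criterion_a": crit_a,
        "criterion_b": crit_b,
        "center_shift_ok": shift_ok,
    }
    return crit_a and crit_b and shift_ok, report
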