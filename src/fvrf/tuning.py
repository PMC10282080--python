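"""Orientation / spatial-frequency tuning by subspace reverse correlation.

Grating frames are projected onto a 32-dimensional polar basis (8 evenly
spaced von Mises functions over orientation, period pi, x 4 raised-cosine
functions on a log-stretched spatial-frequency axis); the grating receptive
field is then estimated with the same penalized regression used for
retinotopic mapping, and a parametric tuning surface

    K(theta, omega) = b + (M - b) * O(theta) * S(omega)
    O(theta) = (exp(kappa*cos^2(theta - theta_hat)) - 1) / (exp(kappa) - 1)
    S(omega) = exp(-(log(1+omega) - log(1+omega_hat))^2 / (2 sigma^2))

is fit to the reconstructed map.  O and S each peak at 1 with minimum 0, so
the curve runs from baseline b to maximum M; O wraps every pi.  Dispersion
parameters are reported as full-width-at-half-height bandwidths.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .datatypes import GratingStimulus
from .gazestim import Grid
from .rfmap import ReceptiveFieldModel, ReceptiveFieldResults

__all__ = [
    "PolarBasis",
    "TuningFit",
    "GratingTuningModel",
    "evaluate_tuning_model",
    "fit_tuning_model",
    "orientation_bandwidth",
    "sf_bandwidth",
    "forward_correlation_temporal",
]


@dataclass
class PolarBasis:
    """8 orientation x 4 spatial-frequency basis, each function peaking at 1.

    Orientation functions are von Mises with period pi, centers pi/8 apart,
    concentration chosen so neighboring functions cross at half height.
    Spatial-frequency functions are raised cosines with centers equally
    spaced in log(1 + omega) over ``sf_range`` and support of one
    inter-center interval on either side.  Blank frames map to the zero
    vector.
    """

    n_ori: int = 8
    n_sf: int = 4
    sf_range: tuple[float, float] = (1.0, 16.0)

    def __post_init__(self) -> None:
        self.ori_centers = np.arange(self.n_ori) * np.pi / self.n_ori
        delta = np.pi / self.n_ori
        self.kappa_b = np.log(2.0) / (1.0 - np.cos(2 * delta))
        self.sf_centers_log = np.linspace(
            np.log1p(self.sf_range[0]), np.log1p(self.sf_range[1]), self.n_sf
        )
        self.sf_delta = self.sf_centers_log[1] - self.sf_centers_log[0]

    @property
    def n_funcs(self) -> int:
        return self.n_ori * self.n_sf

    def ori_eval(self, theta: np.ndarray) -> np.ndarray:
        """(n, n_ori); peak-normalized von Mises, period pi."""
        d = np.asarray(theta)[..., None] - self.ori_centers
        return np.exp(self.kappa_b * (np.cos(2 * d) - 1.0))

    def sf_eval(self, omega: np.ndarray) -> np.ndarray:
        u = np.log1p(np.asarray(omega))[..., None] - self.sf_centers_log
        out = 0.5 * (1.0 + np.cos(np.pi * u / self.sf_delta))
        out[np.abs(u) > self.sf_delta] = 0.0
        return out

    def evaluate(self, theta: np.ndarray, omega: np.ndarray) -> np.ndarray:
        """Map (theta, omega) pairs to 32 coefficients; ordering is
        sf-major (all orientations at the lowest SF first), matching the
        lattice used by the regression's Laplacian penalty."""
        o = self.ori_eval(theta)  # (..., n_ori)
        s = self.sf_eval(omega)  # (..., n_sf)
        return (s[..., :, None] * o[..., None, :]).reshape(
            *np.shape(theta), self.n_funcs
        )

    def lattice_grid(self) -> Grid:
        """Pseudo-grid describing the (sf x orientation) lattice for the
        Laplacian penalty (orientation axis wraps)."""
        return Grid(
            x_centers=self.ori_centers,
            y_centers=self.sf_centers_log,
            spacing=float(np.pi / self.n_ori),
        )


def project_polar_basis(gratings: GratingStimulus,
                        basis: PolarBasis) -> np.ndarray:
    """Frames x 32 design matrix: basis evaluation at each frame's
    (orientation, spatial frequency); blank frames are zero rows."""
    X = np.zeros((gratings.n_frames, basis.n_funcs))
    ok = ~gratings.blank
    X[ok] = basis.evaluate(gratings.orientation[ok], gratings.spatial_freq[ok])
    return X


# ---------------------------------------------------------------------------
# parametric tuning model
# ---------------------------------------------------------------------------

def evaluate_tuning_model(b, M, kappa, sigma, theta_hat, omega_hat,
                          theta, omega):
    """Rate at (theta, omega) under the separable tuning surface; equals M
    at the preferred grating and b where either factor vanishes."""
    O = (np.exp(kappa * np.cos(np.asarray(theta) - theta_hat) ** 2) - 1.0) / (
        np.exp(kappa) - 1.0
    )
    S = np.exp(
        -((np.log1p(np.asarray(omega)) - np.log1p(omega_hat)) ** 2)
        / (2.0 * sigma**2)
    )
    return b + (M - b) * O * S


def orientation_bandwidth(kappa: float) -> float:
    """Full width at half height of the orientation factor, radians.
    Tends to pi/2 as kappa -> 0."""
    c2 = np.log1p((np.exp(kappa) - 1.0) / 2.0) / kappa
    return float(2.0 * np.arccos(np.sqrt(c2)))


def sf_bandwidth(sigma: float, omega_hat: float) -> float:
    """Full width at half height of the log-Gaussian SF factor, cyc/deg."""
    half = sigma * np.sqrt(2.0 * np.log(2.0))
    lo = (1.0 + omega_hat) * np.exp(-half) - 1.0
    hi = (1.0 + omega_hat) * np.exp(half) - 1.0
    return float(hi - max(lo, 0.0) if lo > -1 else hi)


@dataclass
class TuningFit:
    b: float
    M: float
    kappa: float
    sigma: float
    theta_hat: float  # rad, mod pi
    omega_hat: float  # cyc/deg
    ori_bandwidth: float
    sf_bandwidth: float
    r2: float

    def __call__(self, theta, omega):
        return evaluate_tuning_model(
            self.b, self.M, self.kappa, self.sigma,
            self.theta_hat, self.omega_hat, theta, omega,
        )

    def half_height_region(self, theta, omega) -> np.ndarray:
        """True where both normalized factors exceed one half."""
        O = (np.exp(self.kappa * np.cos(np.asarray(theta) - self.theta_hat) ** 2)
             - 1.0) / (np.exp(self.kappa) - 1.0)
        S = np.exp(
            -((np.log1p(np.asarray(omega)) - np.log1p(self.omega_hat)) ** 2)
            / (2.0 * self.sigma**2)
        )
        return (O >= 0.5) & (S >= 0.5)


def fit_tuning_model(
    tuning_map: np.ndarray,
    theta: np.ndarray,
    omega: np.ndarray,
    n_starts_per_ori: int = 1,
    seed: int = 0,
) -> TuningFit:
    """Nonlinear least-squares fit of the parametric tuning surface to a
    sampled (theta x omega) map, with multi-start over preferred
    orientation.

    tuning_map : (n_theta, n_omega) rates
    theta, omega : the sample axes
    """
    tt, ww = np.meshgrid(theta, omega, indexing="ij")
    z = tuning_map.ravel()
    b0 = max(float(z.min()), 0.0)
    M0 = float(z.max())
    i_pk = int(np.argmax(tuning_map.max(axis=1)))
    j_pk = int(np.argmax(tuning_map[i_pk]))

    def resid(p):
        b, dM, kappa, sigma, th, om = p
        return evaluate_tuning_model(b, b + dM, kappa, sigma, th, om,
                                     tt.ravel(), ww.ravel()) - z

    lb = [0.0, 0.0, 1e-3, 0.02, -np.pi, 0.05]
    ub = [np.inf, np.inf, 30.0, 3.0, 2 * np.pi, 64.0]
    rng = np.random.default_rng(seed)
    starts = [np.array([b0, max(M0 - b0, 1e-3), 2.0, 0.4,
                        float(theta[i_pk]), float(omega[j_pk])])]
    for th0 in np.arange(8) * np.pi / 8:
        for _ in range(n_starts_per_ori):
            starts.append(np.array([
                b0, max(M0 - b0, 1e-3),
                rng.uniform(0.5, 5.0), rng.uniform(0.1, 0.8),
                th0, float(omega[j_pk]) * rng.uniform(0.7, 1.4),
            ]))
    best = None
    for p0 in starts:
        try:
            res = least_squares(resid, np.clip(p0, lb, ub), bounds=(lb, ub),
                                max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("tuning fit diverged from all starts")
    b, dM, kappa, sigma, th, om = best.x
    pred = evaluate_tuning_model(b, b + dM, kappa, sigma, th, om,
                                 tt.ravel(), ww.ravel())
    ss_tot = ((z - z.mean()) ** 2).sum()
    r2 = 1.0 - ((pred - z) ** 2).sum() / ss_tot if ss_tot > 0 else 0.0
    return TuningFit(
        b=float(b), M=float(b + dM), kappa=float(kappa), sigma=float(sigma),
        theta_hat=float(th % np.pi), omega_hat=float(om),
        ori_bandwidth=orientation_bandwidth(kappa),
        sf_bandwidth=sf_bandwidth(sigma, om),
        r2=float(r2),
    )


# ---------------------------------------------------------------------------
# model wrapper
# ---------------------------------------------------------------------------

class GratingTuningModel:
    """Subspace reverse correlation on the polar basis.

    ``fit()`` runs the penalized regression (same contract as retinotopic
    mapping, with the Laplacian over the sf x orientation lattice, wrapping
    orientation); ``tuning(results)`` reconstructs the tuning surface at the
    peak lag and fits the parametric model.
    """

    def __init__(self, gratings: GratingStimulus, counts: np.ndarray,
                 basis: PolarBasis | None = None, n_lags: int = 8):
        self.gratings = gratings
        self.basis = basis or PolarBasis()
        self.design = project_polar_basis(gratings, self.basis)
        self.counts = np.asarray(counts, dtype=float)
        self._rf = ReceptiveFieldModel(
            self.design, counts, n_lags=n_lags,
            grid=self.basis.lattice_grid(),
            frame_rate=gratings.frame_rate, wrap_x=True,
        )

    def fit(self, lambda_grid: np.ndarray | None = None) -> ReceptiveFieldResults:
        return self._rf.fit(lambda_grid)

    def tuning(
        self,
        results: ReceptiveFieldResults,
        unit: int = 0,
        n_theta: int = 36,
        n_omega: int = 24,
    ) -> TuningFit:
        """Reconstruct the rate surface at the peak lag on a (theta, omega)
        sample grid and fit the parametric tuning model.  The regression was
        run on mean-subtracted rates, so the unit's mean rate is added back
        before fitting."""
        k = results.params[:, unit].reshape(self._rf.n_lags, -1)
        kpk = k[results.peak_lag(unit)]
        theta = np.arange(n_theta) * np.pi / n_theta
        omega = np.geomspace(self.basis.sf_range[0] * 0.75,
                             self.basis.sf_range[1], n_omega)
        tt, ww = np.meshgrid(theta, omega, indexing="ij")
        B = self.basis.evaluate(tt, ww)
        mean_rate = self.counts.mean() * self.gratings.frame_rate
        tuning_map = (B @ kpk) * self.gratings.frame_rate + mean_rate
        return fit_tuning_model(tuning_map, theta, omega)


def forward_correlation_temporal(
    gratings: GratingStimulus,
    counts: np.ndarray,
    fit: TuningFit,
    n_lags: int = 12,
) -> dict:
    """Lag-triggered mean firing rate (spikes/s) following onsets of
    preferred gratings — frames whose (theta, omega) lies inside the fitted
    half-height region — with a baseline from blank-frame onsets."""
    counts = np.asarray(counts, dtype=float)
    ok = ~gratings.blank
    pref = np.zeros(gratings.n_frames, dtype=bool)
    pref[ok] = fit.half_height_region(
        gratings.orientation[ok], gratings.spatial_freq[ok]
    )
    rate = counts * gratings.frame_rate

    def triggered(onsets: np.ndarray) -> np.ndarray:
        out = np.full(n_lags, np.nan)
        idx = np.nonzero(onsets)[0]
        for lag in range(n_lags):
            sel = idx[idx + lag < rate.size]
            if sel.size:
                out[lag] = rate[sel + lag].mean()
        return out

    return {
        "lags": np.arange(n_lags),
        "lag_s": np.arange(n_lags) / gratings.frame_rate,
        "preferred": triggered(pref),
        "blank": triggered(gratings.blank),
        "n_preferred_onsets": int(pref.sum()),
    }
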