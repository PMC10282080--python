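"""High-resolution spike-triggered averages and simple/complex
classification on gaze-corrected ROI movies.

The STA at lag tau is the spike-count-weighted mean of the (per-pixel
mean-centered) stimulus frames tau frames before each spike,

    STA(tau) = (1/N) sum_t c_t * S(t - tau),

computed only from frames passing the analysis mask (a spike at frame t
contributes to lag tau only when both t and t - tau are unmasked).
Significance is assessed against a null distribution built from spikes that
carry no stimulus information (pre-onset spikes, emulated by assigning the
same number of spikes to random valid frames), using the maximum absolute
STA value as the test statistic and a p < 0.001 criterion.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STAResult",
    "compute_sta",
    "squared_sta",
    "sta_significance",
    "classify_simple_complex",
]


@dataclass
class STAResult:
    sta: np.ndarray  # (n_lags, h, w) raw
    z: np.ndarray  # z-scored copy
    n_spikes: float
    n_lags: int
    norm_constants: np.ndarray  # per-lag scalar SD used for z-scoring
    p_value: float | None = None
    significant: bool | None = None

    @property
    def peak_lag(self) -> int:
        return int(np.argmax(np.abs(self.sta).reshape(self.n_lags, -1).max(axis=1)))

    def peak_frame(self) -> np.ndarray:
        return self.sta[self.peak_lag]


def _valid_spike_weights(counts: np.ndarray, mask: np.ndarray | None,
                         lag: int) -> np.ndarray:
    """Per-frame spike weights eligible at this lag (spike frame and
    stimulus frame both unmasked, stimulus frame in range)."""
    T = counts.shape[0]
    w = counts.astype(float).copy()
    if mask is not None:
        w = w * mask
        w[lag:] = w[lag:] * mask[: T - lag]
    w[:lag] = 0.0
    return w


def compute_sta(
    movie: np.ndarray,
    counts: np.ndarray,
    n_lags: int = 12,
    mask: np.ndarray | None = None,
    norm_constants: np.ndarray | None = None,
) -> STAResult:
    """Spike-triggered average of a (T, h, w) movie over ``n_lags`` lags.

    ``norm_constants`` (per-lag SD of the null STA) may be supplied so that
    pre- and post-calibration STAs are z-scored with the SAME constants and
    remain comparable; by default they are derived from the movie's pixel
    variance and the per-lag spike counts.
    """
    counts = np.asarray(counts, dtype=float)
    T, h, w = movie.shape
    if counts.shape[0] != T:
        raise ValueError("counts/movie length mismatch")
    keep = np.ones(T, dtype=bool) if mask is None else mask.astype(bool)
    S = movie - movie[keep].mean(axis=0, keepdims=True)
    Sf = S.reshape(T, -1)
    sta = np.zeros((n_lags, h * w))
    n_per_lag = np.zeros(n_lags)
    for lag in range(n_lags):
        wgt = _valid_spike_weights(counts, keep, lag)
        N = wgt.sum()
        n_per_lag[lag] = N
        if N > 0:
            sta[lag] = (wgt[lag:] @ Sf[: T - lag]) / N
    if n_per_lag.max() <= 0:
        raise ValueError("no spikes available after masking")
    if norm_constants is None:
        px_sd = Sf[keep].std()
        norm_constants = px_sd / np.sqrt(np.maximum(n_per_lag, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = sta / np.where(norm_constants > 0, norm_constants, np.inf)[:, None]
    return STAResult(
        sta=sta.reshape(n_lags, h, w),
        z=z.reshape(n_lags, h, w),
        n_spikes=float(counts[keep].sum()),
        n_lags=n_lags,
        norm_constants=np.asarray(norm_constants, dtype=float),
    )


def squared_sta(
    movie: np.ndarray,
    counts: np.ndarray,
    n_lags: int = 12,
    mask: np.ndarray | None = None,
    norm_constants: np.ndarray | None = None,
) -> STAResult:
    """STA on squared (energy) pixel values — sensitive to phase-invariant
    units whose linear STA averages to zero."""
    return compute_sta(movie**2, counts, n_lags=n_lags, mask=mask,
                       norm_constants=norm_constants)


def sta_significance(
    movie: np.ndarray,
    counts: np.ndarray,
    n_lags: int = 12,
    mask: np.ndarray | None = None,
    n_null: int = 1000,
    seed: int = 0,
    alpha: float = 0.001,
    squared: bool = False,
) -> STAResult:
    """STA with a permutation-style significance test.

    Test statistic: max absolute raw STA value over lags and pixels.  Null:
    the same statistic when the unit's N spikes are assigned uniformly to
    valid frames (spikes that by construction carry no stimulus
    information, as with pre-stimulus-onset spikes); p is the exceedance
    fraction with the +1 correction, significant iff p < ``alpha``.
    """
    rng = np.random.default_rng(seed)
    counts = np.asarray(counts, dtype=float)
    T = movie.shape[0]
    keep = np.ones(T, dtype=bool) if mask is None else mask.astype(bool)
    src = movie**2 if squared else movie
    res = compute_sta(src, counts, n_lags=n_lags, mask=mask)
    obs = float(np.abs(res.sta).max())

    S = src - src[keep].mean(axis=0, keepdims=True)
    Sf = S.reshape(T, -1)
    N = int(round(counts[keep].sum()))
    valid_idx = np.nonzero(keep)[0]
    probs = np.full(valid_idx.size, 1.0 / valid_idx.size)
    C = rng.multinomial(N, probs, size=n_null).astype(float)  # (n_null, n_valid)
    Cfull = np.zeros((n_null, T))
    Cfull[:, valid_idx] = C
    null_stat = np.zeros(n_null)
    for lag in range(n_lags):
        Wl = Cfull[:, lag:] * keep[: T - lag]
        Nl = Wl.sum(axis=1)
        Nl[Nl == 0] = 1.0
        stas = (Wl @ Sf[: T - lag]) / Nl[:, None]
        null_stat = np.maximum(null_stat, np.abs(stas).max(axis=1))
    p = float((1 + (null_stat >= obs).sum()) / (1 + n_null))
    res.p_value = p
    res.significant = bool(p < alpha)
    return res


# ---------------------------------------------------------------------------
# simple / complex classification
# ---------------------------------------------------------------------------

def _fit_rate_params(feature: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Poisson MLE of rate = b + a * feature (a, b >= 0), L-BFGS on log
    parameters with analytic gradients."""
    from scipy.optimize import minimize

    fsd = feature.std() + 1e-12
    f = feature / fsd

    def nll_grad(p):
        a, b = np.exp(p)
        r = b + a * f + 1e-9
        nll = (r - y * np.log(r)).sum()
        drdr = 1.0 - y / r
        return nll, np.array([a * (drdr * f).sum(), b * drdr.sum()])

    y_mean = max(y.mean(), 1e-6)
    fm = max(f.mean(), 1e-6)
    best = None
    for a_frac in (0.9, 0.3):
        a0 = a_frac * y_mean / fm
        b0 = max(y_mean - a0 * fm, 1e-4 * y_mean)
        res = minimize(nll_grad, np.log([a0, b0]), jac=True, method="L-BFGS-B",
                       options={"maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(best.x)
    return float(a / fsd), float(b)


def _heldout_ll(feature_te, y_te, a, b) -> float:
    r = b + a * feature_te + 1e-9
    return float((y_te * np.log(r) - r).sum())


def classify_simple_complex(
    movie: np.ndarray,
    counts: np.ndarray,
    n_folds: int = 2,
    lag: int | None = None,
    mask: np.ndarray | None = None,
) -> tuple[str, float]:
    """Label a unit 'simple' or 'complex' by cross-validated likelihood.

    The simple model is a single linear filter (the training-fold STA)
    followed by half-squaring; the complex model is the energy of a
    quadrature-style filter pair (the top two eigenvectors of the
    spike-triggered covariance).  Both feed rate = b + a*drive with Poisson
    observations; the unit takes the label of the model with the higher
    summed held-out log-likelihood (relative to the intercept-only model —
    'unclassified' if neither beats it).

    Returns (label, delta_cvLL = LL_simple - LL_complex).
    """
    if n_folds < 2:
        raise ValueError("need >= 2 folds")
    counts = np.asarray(counts, dtype=float)
    T = movie.shape[0]
    keep = np.ones(T, dtype=bool) if mask is None else mask.astype(bool)
    if lag is None:
        # the squared (energy) STA locates the response lag for phase-
        # sensitive and phase-invariant units alike
        lag = squared_sta(movie, counts, n_lags=8, mask=mask).peak_lag
    S = (movie - movie.mean(axis=0, keepdims=True)).reshape(T, -1)
    # pair stimulus frame t-lag with counts at t
    X = S[: T - lag]
    y = counts[lag:]
    ok = keep[lag:] & keep[: T - lag]
    X, y = X[ok], y[ok]

    folds = np.array_split(np.arange(len(y)), n_folds)
    ll_simple = ll_complex = ll_null = 0.0
    for f in range(n_folds):
        te = folds[f]
        tr = np.concatenate([folds[g] for g in range(n_folds) if g != f])
        Xtr, ytr = X[tr], y[tr]
        Xte, yte = X[te], y[te]
        N = ytr.sum()
        if N < 10:
            continue
        sta = (ytr @ Xtr) / N
        w = sta / (np.linalg.norm(sta) + 1e-12)
        # spike-triggered covariance (mean-removed) for the energy pair
        Xc = Xtr - (ytr @ Xtr)[None, :] / N
        C_spk = (Xc * ytr[:, None]).T @ Xc / N
        C_all = Xtr.T @ Xtr / len(ytr)
        evals, evecs = np.linalg.eigh(C_spk - C_all)
        pair = evecs[:, np.argsort(evals)[-2:]]
        # simple: half-squared projection
        fs_tr = np.clip(Xtr @ w, 0, None) ** 2
        fs_te = np.clip(Xte @ w, 0, None) ** 2
        a, b = _fit_rate_params(fs_tr, ytr)
        ll_simple += _heldout_ll(fs_te, yte, a, b)
        # complex: energy of the pair
        fc_tr = ((Xtr @ pair) ** 2).sum(axis=1)
        fc_te = ((Xte @ pair) ** 2).sum(axis=1)
        a, b = _fit_rate_params(fc_tr, ytr)
        ll_complex += _heldout_ll(fc_te, yte, a, b)
        mu = max(ytr.mean(), 1e-9)
        ll_null += float((yte * np.log(mu) - mu).sum())
    delta = ll_simple - ll_complex
    if max(ll_simple, ll_complex) <= ll_null:
        return "unclassified", float(delta)
    return ("simple" if delta > 0 else "complex"), float(delta)
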