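"""Neural eye-tracker calibration.

A population encoding model — a convolutional feature core, a factorized
per-neuron spatial x feature readout, and a 2-layer "shifter" network that
maps the measured gaze position to a single shift shared by every neuron's
readout — is fit to gaze-contingent stimulus movies and spikes by minimizing
the Poisson negative log-likelihood with Adam.  Systematic calibration error
in the tracker appears as a gaze-dependent displacement of ALL receptive
fields in the movie; the shared shift absorbs exactly that component, and
evaluating the trained shifter on a lattice of gaze positions yields a
calibration-correction grid.

The shifter output is constrained to zero at gaze (0, 0).  This pins the
gauge of an intrinsic degeneracy: a gaze-independent (constant) shift is
indistinguishable from relocating every readout; ``absolute_correction_grid``
resolves the constant using known RF anchor positions when ground truth is
available (synthetic sessions).  The model is used ONLY to produce the
correction — downstream receptive fields are conventional spike-triggered
averages on the corrected stimulus, never model outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .datatypes import EyeTrace
from .nnet import (
    Adam,
    BatchNorm2d,
    Conv2dSame,
    Linear,
    Param,
    ReLU,
    Softplus,
    softplus,
    softplus_grad,
)

__all__ = [
    "EncodingModelConfig",
    "ShifterNetwork",
    "GazeCalibrationModel",
    "GazeCalibrationResults",
    "CalibrationGrid",
    "apply_correction",
    "absolute_correction_grid",
]


@dataclass
class EncodingModelConfig:
    """Architecture of the encoding model.

    Core: ``len(kernels)`` convolutional layers (ReLU + batch norm each),
    ``channels`` feature maps per layer, Hamming-tapered kernels.  Time is
    embedded through the input channels (``n_lags`` movie frames).  The
    shifter is a 2-layer MLP, ``shifter_hidden`` softplus units then 2
    linear outputs, pinned to (0, 0) at gaze (0, 0).
    """

    channels: int = 20
    kernels: tuple[int, ...] = (11, 9, 7, 7)
    shifter_hidden: int = 20
    n_lags: int = 4


class ShifterNetwork:
    """gaze (d.v.a) -> shared readout shift (d.v.a), exactly 0 at (0, 0).

    The raw 2-layer output is squashed through cap*tanh(./cap) before the
    origin subtraction, so the correction saturates smoothly at a physical
    bound (default 1 d.v.a per component) instead of extrapolating without
    limit outside the region the gaze data covers.
    """

    def __init__(self, hidden: int, rng, cap: float = 1.0):
        self.l1 = Linear(2, hidden, rng)
        self.act = Softplus()
        self.l2 = Linear(hidden, 2, rng)
        self.l2.W.val[...] = 0.0  # start as the identity calibration
        self.l2.b.val[...] = 0.0
        self.cap = cap
        self._tanh = None

    def params(self):
        return self.l1.params() + self.l2.params()

    def forward(self, gaze: np.ndarray, train: bool = True) -> np.ndarray:
        # append the origin; subtracting its output enforces the constraint
        g = np.vstack([gaze, np.zeros((1, 2))])
        raw = self.l2.forward(
            self.act.forward(self.l1.forward(g, train), train), train
        )
        t = np.tanh(raw / self.cap)
        self._tanh = t
        out = self.cap * t
        return out[:-1] - out[-1]

    def backward(self, dout: np.ndarray) -> None:
        d = np.vstack([dout, -dout.sum(axis=0, keepdims=True)])
        d = d * (1.0 - self._tanh**2)
        self.l1.backward(self.act.backward(self.l2.backward(d)))


def _interp_matrix(n: int, shift: float) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear 1D sampling matrix M (out = M @ signal sampled at i + shift)
    and its derivative dM/dshift.  Out-of-range samples clamp to the border
    (derivative cancels there)."""
    p = np.arange(n) + shift
    p0 = np.floor(p).astype(int)
    w = p - p0
    i0 = np.clip(p0, 0, n - 1)
    i1 = np.clip(p0 + 1, 0, n - 1)
    rows = np.arange(n)
    M = np.zeros((n, n))
    dM = np.zeros((n, n))
    np.add.at(M, (rows, i0), 1.0 - w)
    np.add.at(M, (rows, i1), w)
    np.add.at(dM, (rows, i0), -1.0)
    np.add.at(dM, (rows, i1), 1.0)
    return M, dM


class GazeCalibrationModel:
    """Encoding model (core + factorized readout + shifter) for eye-tracker
    recalibration.

    Parameters
    ----------
    roi_shape : (h, w) movie pixels
    n_neurons : simultaneously recorded units (>= 2; the shared shift is
        identified by the population, and identification improves with more
        units)
    pitch : d.v.a per movie pixel
    config : EncodingModelConfig
    """

    def __init__(self, roi_shape: tuple[int, int], n_neurons: int,
                 pitch: float, config: EncodingModelConfig | None = None,
                 seed: int = 0):
        cfg = config or EncodingModelConfig()
        if n_neurons < 2:
            raise ValueError("need >= 2 neurons to identify the shared shift")
        if min(roi_shape) < max(cfg.kernels):
            raise ValueError("ROI smaller than the largest convolution kernel")
        self.cfg = cfg
        self.roi_shape = tuple(roi_shape)
        self.n_neurons = n_neurons
        self.pitch = pitch
        rng = np.random.default_rng(seed)
        self.core: list = []
        c_in = cfg.n_lags
        for i, k in enumerate(cfg.kernels):
            self.core.append(
                Conv2dSame(c_in, cfg.channels, k, rng, window=True,
                           need_input_grad=(i > 0))
            )
            self.core.append(ReLU())
            self.core.append(BatchNorm2d(cfg.channels))
            c_in = cfg.channels
        h, w = roi_shape
        self.spat = Param(rng.normal(0.0, 0.05, size=(n_neurons, h, w)))
        self.feat = Param(rng.normal(0.0, 0.2, size=(n_neurons, cfg.channels)))
        self.bias = Param(np.zeros(n_neurons))
        self.shifter = ShifterNetwork(cfg.shifter_hidden, rng)
        self._cache = None

    # -- parameters --------------------------------------------------------
    def params(self) -> list[Param]:
        ps: list[Param] = []
        for layer in self.core:
            ps.extend(layer.params())
        ps.extend([self.spat, self.feat, self.bias])
        ps.extend(self.shifter.params())
        return ps

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    def get_state(self) -> list[np.ndarray]:
        return [p.val.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.val[...] = v

    # -- forward / backward ------------------------------------------------
    def forward(self, clips: np.ndarray, gaze: np.ndarray,
                train: bool = True) -> np.ndarray:
        """clips: (B, n_lags, h, w) movie history; gaze: (B, 2) d.v.a.
        Returns per-neuron nonnegative rates (B, N), spikes/frame."""
        B = clips.shape[0]
        h, w = self.roi_shape
        x = clips
        for layer in self.core:
            x = layer.forward(x, train)
        F = x  # (B, C, h, w)
        shift = self.shifter.forward(gaze, train)  # (B, 2) d.v.a
        dx_px = shift[:, 0] / self.pitch
        dy_px = shift[:, 1] / self.pitch
        Rm = np.empty((B, h, h), dtype=np.float32)
        dRm = np.empty((B, h, h), dtype=np.float32)
        Cm = np.empty((B, w, w), dtype=np.float32)
        dCm = np.empty((B, w, w), dtype=np.float32)
        for b in range(B):
            Rm[b], dRm[b] = _interp_matrix(h, -dy_px[b])  # +y up = -rows
            Cm[b], dCm[b] = _interp_matrix(w, dx_px[b])
        G = np.einsum("bij,bcjk,blk->bcil", Rm, F, Cm, optimize=True)
        Q = np.einsum("bchw,nhw->bcn", G, self.spat.val, optimize=True)
        z = np.einsum("bcn,nc->bn", Q, self.feat.val) + self.bias.val
        rate = softplus(z)
        self._cache = (clips, F, G, Q, z, Rm, dRm, Cm, dCm, shift)
        return rate

    def poisson_loss(self, rate: np.ndarray, counts: np.ndarray) -> float:
        eps = 1e-8
        return float((rate - counts * np.log(rate + eps)).sum() / rate.shape[0])

    def backward(self, counts: np.ndarray, shifter_only: bool = False) -> None:
        clips, F, G, Q, z, Rm, dRm, Cm, dCm, shift = self._cache
        B = z.shape[0]
        eps = 1e-8
        rate = softplus(z)
        dz = softplus_grad(z) * (1.0 - counts / (rate + eps)) / B
        self.bias.grad += dz.sum(axis=0)
        self.feat.grad += np.einsum("bn,bcn->nc", dz, Q)
        dQ = dz[:, None, :] * self.feat.val.T[None, :, :]  # (B, C, N)
        self.spat.grad += np.einsum("bcn,bchw->nhw", dQ, G, optimize=True)
        dG = np.einsum("bcn,nhw->bchw", dQ, self.spat.val, optimize=True)
        # gradients through the bilinear resampling
        Gy = np.einsum("bij,bcjk,blk->bcil", dRm, F, Cm, optimize=True)
        Gx = np.einsum("bij,bcjk,blk->bcil", Rm, F, dCm, optimize=True)
        ddy_px = -np.einsum("bchw,bchw->b", dG, Gy)  # row shift = -dy
        ddx_px = np.einsum("bchw,bchw->b", dG, Gx)
        dshift = np.column_stack([ddx_px, ddy_px]) / self.pitch
        self.shifter.backward(dshift)
        if shifter_only:
            return
        dF = np.einsum("bij,bcil,blk->bcjk", Rm, dG, Cm, optimize=True)
        dx = dF
        for layer in reversed(self.core):
            dx = layer.backward(dx)

    def _clip_shifter_grads(self, max_norm: float = 5.0) -> None:
        # the shifter sees noisy, occasionally huge gradients early in
        # training; clipping keeps a bad minibatch from derailing it
        for p in self.shifter.params():
            n = float(np.linalg.norm(p.grad))
            if n > max_norm:
                p.grad *= max_norm / n

    # -- training ----------------------------------------------------------
    def fit(
        self,
        movie: np.ndarray,
        gaze: np.ndarray,
        counts: np.ndarray,
        frame_mask: np.ndarray | None = None,
        n_steps: int = 1500,
        batch_size: int = 32,
        lr: float = 2e-3,
        shifter_lr: float = 1e-2,
        val_frac: float = 0.2,
        eval_every: int = 50,
        patience: int = 8,
        val_subsample: int = 512,
        init_readout_sta: bool = True,
        polish_steps: int = 400,
        polish_batch: int = 64,
        seed: int = 0,
    ) -> "GazeCalibrationResults":
        """Train all components jointly on (movie, gaze, spikes).

        movie : (T, h, w) gaze-contingent stimulus (mean gray = 0)
        gaze : (T, 2) measured gaze, d.v.a
        counts : (T, N) spike counts per frame
        frame_mask : frames eligible as prediction targets

        The last ``val_frac`` time block is held out; training stops early
        when validation Poisson loss stops improving (best parameters are
        restored).  Returns a results object wrapping the fitted model.
        """
        T = movie.shape[0]
        L = self.cfg.n_lags
        movie = movie - movie.mean(axis=0, keepdims=True)
        sd = movie.std() + 1e-9
        movie = (movie / sd).astype(np.float32)
        ok = np.ones(T, dtype=bool) if frame_mask is None else frame_mask.copy()
        ok[: L - 1] = False
        idx_all = np.nonzero(ok)[0]
        n_tr = int(round(len(idx_all) * (1 - val_frac)))
        tr_idx, va_idx = idx_all[:n_tr], idx_all[n_tr:]
        rng = np.random.default_rng(seed)
        if len(va_idx) > val_subsample:
            va_idx = np.sort(rng.choice(va_idx, val_subsample, replace=False))

        # start each unit's output at its mean rate (inverse softplus)
        mu0 = np.clip(counts[idx_all].mean(axis=0), 1e-3, None)
        self.bias.val[...] = np.log(np.expm1(mu0))

        if init_readout_sta:
            # seed each unit's spatial readout with its stimulus-energy STA
            # so the shifter sees informative gradients from the start
            from scipy.ndimage import gaussian_filter

            h, w = self.roi_shape
            Sf = movie.reshape(T, -1)
            S2 = Sf**2
            S2 = S2 - S2.mean(axis=0, keepdims=True)
            acc = np.zeros((self.n_neurons, h * w), dtype=np.float32)
            for lag in range(L):
                wgt = counts[lag:]
                norm = np.maximum(wgt.sum(axis=0), 1.0)[:, None]
                acc += np.abs(wgt.T @ Sf[: T - lag]) / norm
                acc += np.abs(wgt.T @ S2[: T - lag]) / norm
            for u in range(self.n_neurons):
                m = gaussian_filter(acc[u].reshape(h, w), 1.0)
                m = m - np.median(m)
                m = np.clip(m, 0, None)
                peak = m.max()
                if peak > 0:
                    self.spat.val[u] = 0.5 * m / peak

        def clips_for(idx: np.ndarray) -> np.ndarray:
            # channel 0 = current frame, channel l = l frames back
            return np.stack(
                [np.stack([movie[i - l] for l in range(L)]) for i in idx]
            )

        def val_loss() -> float:
            tot, n = 0.0, 0
            for s in range(0, len(va_idx), 64):
                sub = va_idx[s : s + 64]
                r = self.forward(clips_for(sub), gaze[sub], train=False)
                tot += (r - counts[sub] * np.log(r + 1e-8)).sum()
                n += len(sub)
            return tot / max(n, 1)

        opt = Adam(
            self.params(), lr=lr,
            lr_overrides={id(p): shifter_lr for p in self.shifter.params()},
        )
        loss_trace: list[float] = []
        val_trace: list[float] = []
        best_val = np.inf
        best_state = self.get_state()
        bad = 0
        # intercept-only reference for the failure flag
        mean_rate = counts[tr_idx].mean(axis=0) + 1e-8
        null_val = float(
            (mean_rate[None, :] - counts[va_idx] * np.log(mean_rate[None, :]))
            .sum() / max(len(va_idx), 1)
        )
        warmup = int(0.15 * n_steps)  # let core/readout settle first
        for step in range(n_steps):
            # cosine decay to 10% of the base rate over the run
            decay = 0.1 + 0.45 * (1.0 + np.cos(np.pi * step / max(n_steps, 1)))
            opt.lr = lr * decay
            s_lr = 0.0 if step < warmup else shifter_lr * decay
            opt.lr_overrides = {id(p): s_lr for p in self.shifter.params()}
            batch = rng.choice(tr_idx, size=min(batch_size, len(tr_idx)),
                               replace=False)
            opt.zero_grad()
            r = self.forward(clips_for(batch), gaze[batch], train=True)
            loss_trace.append(self.poisson_loss(r, counts[batch]))
            self.backward(counts[batch])
            self._clip_shifter_grads()
            opt.step()
            if (step + 1) % eval_every == 0 or step == n_steps - 1:
                v = val_loss()
                val_trace.append(v)
                if v < best_val - 1e-6:
                    best_val = v
                    best_state = self.get_state()
                    bad = 0
                else:
                    bad += 1
                    if bad >= patience:
                        break
        self.set_state(best_state)
        if polish_steps > 0:
            # shifter-only polish: core and readout frozen (eval-mode batch
            # norm), so no convolutional backward pass is needed
            snapshot = self.get_state()
            opt2 = Adam(self.shifter.params(), lr=0.3 * shifter_lr)
            for _ in range(polish_steps):
                batch = rng.choice(tr_idx, size=min(polish_batch, len(tr_idx)),
                                   replace=False)
                opt2.zero_grad()
                r = self.forward(clips_for(batch), gaze[batch], train=False)
                loss_trace.append(self.poisson_loss(r, counts[batch]))
                self.backward(counts[batch], shifter_only=True)
                self._clip_shifter_grads()
                opt2.step()
            v = val_loss()
            val_trace.append(v)
            if v < best_val:
                best_val = v
            else:
                self.set_state(snapshot)
        return GazeCalibrationResults(
            model=self,
            loss_trace=np.asarray(loss_trace),
            val_trace=np.asarray(val_trace),
            best_val_loss=float(best_val),
            null_val_loss=null_val,
            failed=bool(best_val >= null_val),
        )


@dataclass
class GazeCalibrationResults:
    """Fitted calibration model, training diagnostics and grid export."""

    model: GazeCalibrationModel
    loss_trace: np.ndarray
    val_trace: np.ndarray
    best_val_loss: float
    null_val_loss: float
    failed: bool  # validation never beat the intercept-only model

    def shift_at(self, gaze: np.ndarray) -> np.ndarray:
        """Shifter output (d.v.a) at gaze positions (n, 2)."""
        return self.model.shifter.forward(np.atleast_2d(gaze), train=False)

    def to_grid(self, span: float = 5.0, spacing: float = 1.0) -> "CalibrationGrid":
        """Evaluate the shifter on a lattice of potential gaze positions
        spanning -span..span d.v.a per axis; corrections stored in arcmin."""
        nodes = np.arange(-span, span + spacing / 2, spacing)
        gx, gy = np.meshgrid(nodes, nodes)  # (ny, nx)
        s = self.shift_at(np.column_stack([gx.ravel(), gy.ravel()]))
        dx = s[:, 0].reshape(gx.shape) * 60.0
        dy = s[:, 1].reshape(gx.shape) * 60.0
        return CalibrationGrid(nodes=nodes, dx_arcmin=dx, dy_arcmin=dy)

    def readout_centroids_px(self) -> np.ndarray:
        """Energy centroid (row, col) of each neuron's spatial readout."""
        w2 = self.model.spat.val**2
        h, wd = self.model.roi_shape
        rows, cols = np.mgrid[0:h, 0:wd]
        tot = w2.sum(axis=(1, 2)) + 1e-12
        r = (w2 * rows).sum(axis=(1, 2)) / tot
        c = (w2 * cols).sum(axis=(1, 2)) / tot
        return np.column_stack([r, c])

    def summary(self) -> str:
        g = self.to_grid()
        mag = np.hypot(g.dx_arcmin, g.dy_arcmin)
        return (
            "Gaze-calibration encoding model\n"
            f"  parameters: {self.model.parameter_count()}\n"
            f"  train steps: {len(self.loss_trace)}, best val Poisson loss "
            f"{self.best_val_loss:.4f} (intercept-only {self.null_val_loss:.4f})"
            f"{'  ** FAILED **' if self.failed else ''}\n"
            f"  correction grid over +-5 d.v.a: median |shift| "
            f"{np.median(mag):.2f} arcmin, max {mag.max():.2f} arcmin"
        )


@dataclass
class CalibrationGrid:
    """Gaze-position-indexed correction field: corrected gaze = measured
    gaze + bilinear interpolation of (dx, dy) at the measured position.
    Node values are in arcmin; queries outside the span clamp to the edge."""

    nodes: np.ndarray  # shared x/y node positions, d.v.a
    dx_arcmin: np.ndarray  # (ny, nx)
    dy_arcmin: np.ndarray

    def shift_at(self, x: np.ndarray, y: np.ndarray):
        """Bilinear interpolation -> (dx, dy) in d.v.a."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = self.nodes
        step = n[1] - n[0]
        fx = np.clip((x - n[0]) / step, 0, len(n) - 1 - 1e-9)
        fy = np.clip((y - n[0]) / step, 0, len(n) - 1 - 1e-9)
        ix = np.floor(fx).astype(int)
        iy = np.floor(fy).astype(int)
        wx = fx - ix
        wy = fy - iy

        def bil(val):
            return (
                val[iy, ix] * (1 - wy) * (1 - wx)
                + val[iy, ix + 1] * (1 - wy) * wx
                + val[iy + 1, ix] * wy * (1 - wx)
                + val[iy + 1, ix + 1] * wy * wx
            ) / 60.0

        return bil(self.dx_arcmin), bil(self.dy_arcmin)

    # -- I/O ---------------------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "nodes_dva": self.nodes.tolist(),
                    "dx_arcmin": self.dx_arcmin.tolist(),
                    "dy_arcmin": self.dy_arcmin.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "CalibrationGrid":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            nodes=np.array(d["nodes_dva"]),
            dx_arcmin=np.array(d["dx_arcmin"]),
            dy_arcmin=np.array(d["dy_arcmin"]),
        )


def apply_correction(trace: EyeTrace, grid: CalibrationGrid) -> EyeTrace:
    """Corrected gaze trace: position + interpolated grid shift."""
    dx, dy = grid.shift_at(trace.x, trace.y)
    return EyeTrace(trace.t.copy(), trace.x + dx, trace.y + dy, trace.rate,
                    trace.valid.copy())


def absolute_correction_grid(
    results: GazeCalibrationResults,
    true_anchors_dva: np.ndarray,
    grid: CalibrationGrid | None = None,
) -> CalibrationGrid:
    """Resolve the constant-shift gauge of a fitted calibration grid.

    A gaze-independent calibration offset is absorbed by the learned readout
    positions (the shifter is pinned to zero at the origin).  Given the true
    retinal anchor of each unit (available for synthetic sessions), the
    offset is recovered as the mean displacement between the learned readout
    centroids and the anchors, and added to every grid node.
    """
    grid = grid or results.to_grid()
    cent = results.readout_centroids_px()
    h, w = results.model.roi_shape
    pitch = results.model.pitch
    exp_col = (w - 1) / 2 + true_anchors_dva[:, 0] / pitch
    exp_row = (h - 1) / 2 - true_anchors_dva[:, 1] / pitch
    off_x = np.mean(cent[:, 1] - exp_col) * pitch * 60.0  # arcmin
    off_y = np.mean(exp_row - cent[:, 0]) * pitch * 60.0
    return CalibrationGrid(
        nodes=grid.nodes.copy(),
        dx_arcmin=grid.dx_arcmin + off_x,
        dy_arcmin=grid.dy_arcmin + off_y,
    )
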