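"""Minimal reverse-mode neural-network layers on numpy.

Just enough machinery for the gaze-calibration encoding model: same-padded
2D convolution (with an optional fixed Hamming taper on the kernels), ReLU,
batch normalization, softplus, dense layers and an Adam optimizer.  Each
layer caches what its backward pass needs; gradients accumulate into
``Param.grad``.
"""
from __future__ import annotations

import numpy as np

try:  # numba accelerates the im2col gather (the training hot spot)
    import numba as _nb

    @_nb.njit(fastmath=True)
    def _im2col_gather(xp, k, H, W, out):  # pragma: no cover - jitted
        B, C, _, _ = xp.shape
        for b in range(B):
            for i in range(H):
                for j in range(W):
                    row = (b * H + i) * W + j
                    col = 0
                    for c in range(C):
                        base = xp[b, c]
                        for u in range(k):
                            for v in range(k):
                                out[row, col] = base[i + u, j + v]
                                col += 1
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "Param",
    "Conv2dSame",
    "ReLU",
    "BatchNorm2d",
    "Softplus",
    "Linear",
    "Adam",
    "hamming2d",
    "softplus",
    "softplus_grad",
]


class Param:
    __slots__ = ("val", "grad")

    def __init__(self, val: np.ndarray):
        self.val = np.asarray(val, dtype=np.float32)
        self.grad = np.zeros_like(self.val)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    @property
    def size(self) -> int:
        return self.val.size


def hamming2d(k: int) -> np.ndarray:
    w = np.hamming(k)
    return np.outer(w, w)


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def softplus_grad(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


class Conv2dSame:
    """Same-padded 2D convolution (cross-correlation) via im2col.

    When ``window=True`` the effective kernel is the weight multiplied by a
    fixed 2D Hamming taper (an anti-aliasing measure for stacked cores).
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng, window: bool = True,
                 need_input_grad: bool = True):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = Param(rng.normal(0.0, scale, size=(c_out, c_in, k, k)))
        self.b = Param(np.zeros(c_out))
        self.k = k
        self.win = hamming2d(k).astype(np.float32) if window else np.ones((k, k), np.float32)
        self.need_input_grad = need_input_grad
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def _weff(self) -> np.ndarray:
        return self.W.val * self.win[None, None]

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        """(B, C, H, W) -> (B*H*W, C*k*k) with zero same-padding."""
        B, C, H, W = x.shape
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        if _HAVE_NUMBA:
            out = np.empty((B * H * W, C * k * k), dtype=xp.dtype)
            return _im2col_gather(xp, k, H, W, out)
        v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # v: (B, C, H, W, k, k) -> (B, H, W, C, k, k)
        return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * H * W, C * k * k
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        B, C, H, W = x.shape
        cols = self._im2col(x, self.k)
        Wm = self._weff().reshape(self.W.val.shape[0], -1).T  # (Ckk, Cout)
        out = cols @ Wm + self.b.val
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(out.reshape(B, H, W, -1).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.asarray(dout, dtype=np.float32)
        cols, xshape = self._cache
        B, C, H, W = xshape
        c_out = dout.shape[1]
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, c_out)
        dW = (cols.T @ dmat).T.reshape(self.W.val.shape)
        self.W.grad += dW * self.win[None, None]
        self.b.grad += dmat.sum(axis=0)
        if not self.need_input_grad:
            return None
        # input gradient: correlate dout with the flipped, transposed kernel
        Wt = self._weff()[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Cin,Cout,k,k)
        dcols = self._im2col(dout, self.k)
        Wm2 = Wt.reshape(C, c_out * self.k * self.k).T
        dx = (dcols @ Wm2).reshape(B, H, W, C).transpose(0, 3, 1, 2)
        return dx


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class BatchNorm2d:
    """Per-channel batch normalization over (batch, H, W)."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.val[None, :, None, None] * xhat + self.beta.val[
            None, :, None, None
        ]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.val[None, :, None, None]
        if not train:
            return dxhat * inv[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (
            inv[None, :, None, None] / m * (m * dxhat - s1 - xhat * s2)
        )


class Softplus:
    def __init__(self):
        self._x = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return softplus(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * softplus_grad(self._x)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng):
        self.W = Param(rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = np.asarray(x, dtype=np.float32)
        return self._x @ self.W.val + self.b.val

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.val.T


class Adam:
    """Adam with an optional per-parameter learning-rate override."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 lr_overrides: dict[int, float] | None = None):
        self.params = params
        self.lr = lr
        self.lr_overrides = lr_overrides or {}
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.val) for p in params]
        self.v = [np.zeros_like(p.val) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            lr = self.lr_overrides.get(id(p), self.lr)
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p.val -= lr * mh / (np.sqrt(vh) + self.eps)
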