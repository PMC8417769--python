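"""Compact NumPy neural-network engine for 3D volumetric segmentation.

Layers operate on single samples laid out channels-first, shape
(C, D, H, W), in float32.  Each layer implements ``forward`` (caching what
its backward pass needs) and ``backward`` (returning the gradient with
respect to its input while accumulating parameter gradients).  Convolutions
are lowered to GEMM through an im2col transform; the input-gradient of a
"same"-padded convolution is computed as a convolution of the output
gradient with the spatially flipped, channel-transposed kernels.

This is deliberately a minimal engine: batch size 1, no graph autodiff —
the U-net wires layer calls explicitly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "BatchNorm3d", "ELU", "MaxPool3d", "ConvTranspose3d", "Adam"]


class Layer:
    """Base layer: parameter registry plus forward/backward protocol."""

    def parameters(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, gradient) triples; values are updated in place."""
        return []

    def state(self) -> dict[str, np.ndarray]:
        """Non-trainable buffers to persist in checkpoints."""
        return {}

    def zero_grad(self) -> None:
        for _, _, g in self.parameters():
            g[...] = 0.0


class Conv3d(Layer):
    """Same-padded 3D convolution with odd kernel size.

    The padded input is flattened to (C, M); a neighbour at spatial offset
    (a, b, c) then sits at a constant flat offset, so each kernel tap is one
    (out_ch, in_ch) GEMM against a contiguous *view* of the flat array — no
    im2col buffer and no per-tap copies.  Flat positions that fall in the
    padding ring accumulate garbage from row wrap-around, but only interior
    positions are extracted (forward) or carry non-zero gradient (backward),
    so the result is exact.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel=(3, 3, 3), rng=None):
        kernel = (kernel,) * 3 if isinstance(kernel, int) else tuple(kernel)
        if any(k % 2 == 0 for k in kernel):
            raise ValueError("kernel sizes must be odd for same padding")
        rng = rng or np.random.default_rng()
        fan_in = in_ch * int(np.prod(kernel))
        self.kernel = kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch) + kernel).astype(
            np.float32
        )
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xf: np.ndarray | None = None
        self._geom: tuple | None = None

    def parameters(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def _geometry(self, spatial):
        d, h, w = spatial
        p1, p2, p3 = (k // 2 for k in self.kernel)
        dp, hp, wp = d + 2 * p1, h + 2 * p2, w + 2 * p3
        s1, s2 = hp * wp, wp
        deltas = [
            a * s1 + b * s2 + c
            for a in range(self.kernel[0])
            for b in range(self.kernel[1])
            for c in range(self.kernel[2])
        ]
        return (d, h, w), (p1, p2, p3), (dp, hp, wp), (s1, s2), deltas

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        spatial, pads, padded, (s1, s2), deltas = self._geometry(x.shape[1:])
        d, h, w = spatial
        xp = np.zeros((self.in_ch,) + padded, dtype=np.float32)
        xp[:, pads[0] : pads[0] + d, pads[1] : pads[1] + h, pads[2] : pads[2] + w] = x
        m = xp[0].size
        xf = xp.reshape(self.in_ch, m)
        if training:
            self._xf, self._geom = xf, (spatial, pads, padded, (s1, s2), deltas, m)
        length = m - deltas[-1]
        wmat = self.w.reshape(self.out_ch, self.in_ch, -1)
        acc = wmat[:, :, 0] @ xf[:, deltas[0] : deltas[0] + length]
        for k in range(1, len(deltas)):
            acc += wmat[:, :, k] @ xf[:, deltas[k] : deltas[k] + length]
        out = np.lib.stride_tricks.as_strided(
            acc,
            shape=(self.out_ch, d, h, w),
            strides=(acc.strides[0], 4 * s1, 4 * s2, 4),
        )
        return out + self.b[:, None, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xf = self._xf
        spatial, pads, padded, (s1, s2), deltas, m = self._geom
        d, h, w = spatial
        centre = pads[0] * s1 + pads[1] * s2 + pads[2]
        gp = np.zeros((self.out_ch,) + padded, dtype=np.float32)
        gp[:, pads[0] : pads[0] + d, pads[1] : pads[1] + h, pads[2] : pads[2] + w] = g
        gf = gp.reshape(self.out_ch, m)
        wmat = self.w.reshape(self.out_ch, self.in_ch, -1)
        dwmat = self.dw.reshape(self.out_ch, self.in_ch, -1)
        dxf = np.zeros((self.in_ch, m), dtype=np.float32)
        for k, delta in enumerate(deltas):
            s = delta - centre
            a0 = max(0, -s)
            span = m - abs(s)
            dwmat[:, :, k] += gf[:, a0 : a0 + span] @ xf[:, a0 + s : a0 + s + span].T
            t = wmat[:, :, k].T @ gf
            if s >= 0:
                dxf[:, s:m] += t[:, : m - s]
            else:
                dxf[:, : m + s] += t[:, -s:]
        self.db += gf.sum(axis=1)
        dxp = dxf.reshape((self.in_ch,) + padded)
        return dxp[
            :, pads[0] : pads[0] + d, pads[1] : pads[1] + h, pads[2] : pads[2] + w
        ].copy()


class BatchNorm3d(Layer):
    """Per-channel normalisation over the spatial axes (batch of one).

    Training uses in-sample statistics and maintains exponential running
    averages; evaluation uses the running statistics.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.95):
        self.eps, self.momentum = eps, momentum
        self.gamma = np.ones(n_ch, dtype=np.float32)
        self.beta = np.zeros(n_ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(n_ch, dtype=np.float32)
        self.run_var = np.ones(n_ch, dtype=np.float32)
        self._cache = None

    def parameters(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def state(self):
        return {"run_mean": self.run_mean, "run_var": self.run_var}

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        sh = (-1, 1, 1, 1)
        if training:
            mean = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            self.run_mean[...] = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var[...] = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv_std.reshape(sh)
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma.reshape(sh) * xhat + self.beta.reshape(sh)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        sh = (-1, 1, 1, 1)
        n = g[0].size
        self.dgamma += (g * xhat).sum(axis=(1, 2, 3))
        self.dbeta += g.sum(axis=(1, 2, 3))
        dxhat = g * self.gamma.reshape(sh)
        s1 = dxhat.sum(axis=(1, 2, 3)).reshape(sh)
        s2 = (dxhat * xhat).sum(axis=(1, 2, 3)).reshape(sh)
        return inv_std.reshape(sh) / n * (n * dxhat - s1 - xhat * s2)


class ELU(Layer):
    """Exponential linear unit, alpha = 1."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        pos = x > 0
        y = np.where(pos, x, np.expm1(np.minimum(x, 0.0)))
        if training:
            self._cache = (pos, y)
        return y.astype(np.float32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        pos, y = self._cache
        return g * np.where(pos, 1.0, y + 1.0).astype(np.float32)


class MaxPool3d(Layer):
    """2x2x2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape}")
        win = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 5, 2, 4, 6)
        flat = win.reshape(c, d // 2, h // 2, w // 2, 8)
        idx = flat.argmax(axis=-1)
        if training:
            self._idx = idx
            self._in_shape = x.shape
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        c, d, h, w = self._in_shape
        flat = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(flat, self._idx[..., None], g[..., None], axis=-1)
        win = flat.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
        return win.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, d, h, w)


class ConvTranspose3d(Layer):
    """2x2x2 transposed convolution with stride 2 (learned upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng=None):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = rng.normal(0.0, np.sqrt(2.0 / (in_ch * 8)), (in_ch, out_ch, 2, 2, 2)).astype(
            np.float32
        )
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def parameters(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._x = x
        _, d, h, w = x.shape
        # t[o,a,b,c,d,h,w] = sum_i W[i,o,a,b,c] x[i,d,h,w]
        t = np.tensordot(self.w, x, axes=([0], [0]))
        y = t.transpose(0, 4, 1, 5, 2, 6, 3).reshape(self.out_ch, 2 * d, 2 * h, 2 * w)
        return (y + self.b.reshape(-1, 1, 1, 1)).astype(np.float32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        _, d2, h2, w2 = g.shape
        d, h, w = d2 // 2, h2 // 2, w2 // 2
        gv = g.reshape(self.out_ch, d, 2, h, 2, w, 2).transpose(0, 2, 4, 6, 1, 3, 5)
        # gv: (out, 2, 2, 2, d, h, w)
        self.dw += np.tensordot(x, gv, axes=([1, 2, 3], [4, 5, 6])).transpose(0, 1, 2, 3, 4)
        self.db += g.sum(axis=(1, 2, 3))
        dx = np.tensordot(self.w, gv, axes=([1, 2, 3, 4], [0, 1, 2, 3]))
        return dx.astype(np.float32)


class Adam:
    """ADAM over a flat list of (value, gradient) array pairs.

    The step-size schedule lr_t = lr / (1 + decay * t) matches the inverse
    time-decay convention of the mainstream Keras-era trainers.
    """

    def __init__(self, params, lr: float = 1e-4, decay: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.decay = lr, decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(v) for v, _ in self.params]
        self.v = [np.zeros_like(v) for v, _ in self.params]

    def step(self) -> None:
        lr_t = self.lr / (1.0 + self.decay * self.t)
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for i, (val, grad) in enumerate(self.params):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * grad * grad
            mhat = self.m[i] / b1c
            vhat = self.v[i] / b2c
            val -= (lr_t * mhat / (np.sqrt(vhat) + self.eps)).astype(val.dtype)
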