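"""Layers with explicit forward/backward passes.

Design notes
------------
* Everything runs in float32; tensors are NCHW ``[batch, maps, rows, time]``
  with ``rows`` = virtual channels before the depthwise stage and 1 after.
* Each layer caches what its backward pass needs during forward; ``backward``
  consumes the gradient w.r.t. its output and returns the gradient w.r.t.
  its input, accumulating parameter gradients into ``Param.grad``.
* The input stage (batch norm on the single input map, time zero-padding and
  the temporal convolution) is fused into one layer so the im2col matrix of
  the raw input can be computed once and reused: a single-map batch norm is
  a scalar affine ``a*x + b``, so the convolution output is
  ``a*(col @ W) + b*(P @ W)`` with ``P`` the window mask of non-padded
  positions.  This removes the dominant per-step cost of the network.
* Convolutions preceding a batch norm carry no additive bias (redundant
  under the norm's shift).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


def _uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    """Fan-in uniform init, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(F32)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ----------------------------------------------------------------------
class StandardizedTemporalConv(Layer):
    """Input batch norm (one map) + ZeroPad2d(pl, pr) + Conv2d (1, k) to c_out maps.

    Input ``[B, 1, D, T]`` -> output ``[B, c_out, D, T]`` (padding chosen so
    time length is preserved: pl + pr == k - 1).
    """

    def __init__(self, c_out: int, k: int, rng: np.random.Generator,
                 eps: float = 1e-5, momentum: float = 0.1):
        self.k = k
        self.pl, self.pr = k // 2, k - 1 - k // 2  # (32, 31) for k = 64
        self.W = Param(_uniform(rng, k, (k, c_out)))
        self.gamma = Param(np.ones(1, dtype=F32))
        self.beta = Param(np.zeros(1, dtype=F32))
        self.eps, self.momentum = eps, momentum
        self.running_mean = 0.0
        self.running_var = 1.0
        # caches
        self._col: np.ndarray | None = None
        self._col_shape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W, self.gamma, self.beta]

    def _pad_cols(self, x: np.ndarray) -> np.ndarray:
        """im2col of the zero-padded raw input: returns [B*D*T, k] float32."""
        B, _, D, T = x.shape
        xp = np.zeros((B, D, T + self.pl + self.pr), dtype=F32)
        xp[:, :, self.pl : self.pl + T] = x[:, 0]
        col = sliding_window_view(xp, self.k, axis=2)  # [B, D, T, k] view
        return np.ascontiguousarray(col).reshape(-1, self.k)

    def _edge_profile(self, T: int) -> np.ndarray:
        """E[t, o] = (P @ W): conv response to an all-ones (unpadded) input."""
        pmask = np.zeros(T + self.pl + self.pr, dtype=F32)
        pmask[self.pl : self.pl + T] = 1.0
        pcol = sliding_window_view(pmask, self.k)  # [T, k]
        self._pcol = np.ascontiguousarray(pcol)
        return self._pcol @ self.W.value  # [T, c_out]

    def forward(self, x: np.ndarray, training: bool, col: np.ndarray | None = None
                ) -> np.ndarray:
        B, _, D, T = x.shape
        self._col_shape = (B, D, T)
        if training:
            mu = float(x.mean())
            var = float(x.var())
            n = x.size
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            unbiased = var * n / max(n - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        a = float(self.gamma.value[0]) * inv_std
        b = float(self.beta.value[0]) - a * mu
        self._a, self._mu, self._inv_std = a, mu, inv_std
        self._col = self._pad_cols(x) if col is None else col
        U = self._col @ self.W.value  # [B*D*T, c_out]
        E = self._edge_profile(T)  # [T, c_out]
        self._U, self._E = U, E
        out = a * U.reshape(B, D, T, -1)
        out += b * E[None, None]
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, g: np.ndarray, need_dx: bool = False) -> np.ndarray | None:
        B, D, T = self._col_shape
        gflat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, g.shape[1])
        a = self._a
        gsum_t = gflat.reshape(B * D, T, -1).sum(axis=0)  # [T, c_out]
        da = float(np.vdot(gflat, self._U))
        db = float(np.vdot(gsum_t, self._E))
        # a = gamma * inv_std ; b = beta - a * mu
        self.gamma.grad[0] += (da - db * self._mu) * self._inv_std
        self.beta.grad[0] += db
        # dW from both the signal and the edge-profile term
        self.W.grad += a * (self._col.T @ gflat)
        self.W.grad += float(self.beta.value[0] - a * self._mu) * (self._pcol.T @ gsum_t)
        if not need_dx:
            return None
        # gradient to the raw input (used by the interpretability path)
        dcol = (gflat @ self.W.value.T) * a  # [B*D*T, k]
        dcol = dcol.reshape(B * D, T, self.k)
        dxp = np.zeros((B * D, T + self.pl + self.pr), dtype=F32)
        for j in range(self.k):
            dxp[:, j : j + T] += dcol[:, :, j]
        dx = dxp[:, self.pl : self.pl + T].reshape(B, 1, D, T)
        return dx


# ----------------------------------------------------------------------
class BatchNorm(Layer):
    """Batch normalization over the given reduction axes (channel-wise)."""

    def __init__(self, c: int, axes: tuple = (0, 2, 3), eps: float = 1e-5,
                 momentum: float = 0.1):
        self.axes = axes
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(c, dtype=F32))
        self.beta = Param(np.zeros(c, dtype=F32))
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def _bshape(self, ndim: int):
        shape = [1] * ndim
        shape[1 if ndim > 1 else 0] = -1
        return shape

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.ndim == 2:
            axes = (0,)
        else:
            axes = self.axes
        self._red_axes = axes
        bs = self._bshape(x.ndim)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // mu.size
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            unbiased = var * n / max(n - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu.reshape(bs)) * inv_std.reshape(bs)
            self._xhat, self._inv_std, self._train = xhat, inv_std, True
            return self.gamma.value.reshape(bs) * xhat + self.beta.value.reshape(bs)
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        self._inv_std, self._train = inv_std, False
        return (x - self.running_mean.reshape(bs)) * (self.gamma.value * inv_std).reshape(bs) \
            + self.beta.value.reshape(bs)

    def backward(self, g: np.ndarray) -> np.ndarray:
        bs = self._bshape(g.ndim)
        axes = self._red_axes
        if not self._train:
            return g * (self.gamma.value * self._inv_std).reshape(bs)
        xhat = self._xhat
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gxh = g * self.gamma.value.reshape(bs)
        mean_g = gxh.mean(axis=axes).reshape(bs)
        mean_gx = (gxh * xhat).mean(axis=axes).reshape(bs)
        return self._inv_std.reshape(bs) * (gxh - mean_g - xhat * mean_gx)


# ----------------------------------------------------------------------
class SpatialDepthwiseConv(Layer):
    """Grouped Conv2d kernel (D, 1): per temporal map, mix the D rows.

    Input ``[B, c_in, D, T]`` -> ``[B, c_in*mult, 1, T]``; weight [c_in, mult, D].
    """

    def __init__(self, c_in: int, D: int, mult: int, rng: np.random.Generator):
        self.c_in, self.D, self.mult = c_in, D, mult
        self.W = Param(_uniform(rng, D, (c_in, mult, D)))

    def params(self) -> list[Param]:
        return [self.W]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, D, T = x.shape
        self._x = x
        out = np.empty((B, C * self.mult, 1, T), dtype=F32)
        for c in range(C):
            # [mult, D] x [B, D, T] -> [mult, B, T]
            oc = np.tensordot(self.W.value[c], x[:, c], axes=([1], [1]))
            out[:, c * self.mult : (c + 1) * self.mult, 0] = oc.transpose(1, 0, 2)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        B, C, D, T = x.shape
        gv = g[:, :, 0, :].reshape(B, C, self.mult, T)
        dx = np.empty_like(x)
        for c in range(C):
            self.W.grad[c] += np.tensordot(gv[:, c], x[:, c], axes=([0, 2], [0, 2]))
            # [B, mult, T] x [mult, D] -> [B, T, D]
            dx[:, c] = np.tensordot(gv[:, c], self.W.value[c], axes=([1], [0])).transpose(0, 2, 1)
        return dx


# ----------------------------------------------------------------------
class TemporalDepthwiseConv(Layer):
    """ZeroPad2d(pl, pr) + grouped Conv2d (1, k): one kernel per map.

    Input ``[B, C, 1, T]`` -> ``[B, C, 1, T]`` (pl + pr == k - 1).
    """

    def __init__(self, C: int, k: int, rng: np.random.Generator):
        self.C, self.k = C, k
        self.pl, self.pr = k // 2 - 1, k - k // 2  # (7, 8) for k = 16
        self.W = Param(_uniform(rng, k, (C, k)))

    def params(self) -> list[Param]:
        return [self.W]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, _, T = x.shape
        self._T = T
        xp = np.zeros((B, C, T + self.pl + self.pr), dtype=F32)
        xp[:, :, self.pl : self.pl + T] = x[:, :, 0]
        win = sliding_window_view(xp, self.k, axis=2)  # [B, C, T, k]
        self._win = win
        out = np.einsum("bctk,ck->bct", win, self.W.value, optimize=True)
        return out[:, :, None, :].astype(F32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, C, _, T = g.shape
        gs = g[:, :, 0, :]
        self.W.grad += np.einsum("bct,bctk->ck", gs, self._win, optimize=True)
        dxp = np.zeros((B, C, T + self.pl + self.pr), dtype=F32)
        for j in range(self.k):
            dxp[:, :, j : j + T] += gs * self.W.value[:, j][None, :, None]
        return dxp[:, :, None, self.pl : self.pl + T]


class PointwiseConv(Layer):
    """Conv2d (1, 1): linear map across maps.  [B, c_in, 1, T] -> [B, c_out, 1, T]."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = Param(_uniform(rng, c_in, (c_out, c_in)))

    def params(self) -> list[Param]:
        return [self.W]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        out = np.tensordot(self.W.value, x[:, :, 0, :], axes=([1], [1]))  # [c_out, B, T]
        return np.ascontiguousarray(out.transpose(1, 0, 2))[:, :, None, :]

    def backward(self, g: np.ndarray) -> np.ndarray:
        gs = g[:, :, 0, :]
        x = self._x[:, :, 0, :]
        self.W.grad += np.tensordot(gs, x, axes=([0, 2], [0, 2]))
        dx = np.tensordot(gs, self.W.value, axes=([1], [0]))  # [B, T, c_in]
        return np.ascontiguousarray(dx.transpose(0, 2, 1))[:, :, None, :]


# ----------------------------------------------------------------------
class ELU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0))).astype(F32)
        self._out, self._pos = out, x > 0
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * np.where(self._pos, F32(1.0), self._out + F32(1.0))


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        self.out = np.where(self._mask, x, F32(0.0))
        return self.out

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, F32(0.0))


class AvgPoolTime(Layer):
    """Average pooling (1, p) with stride p; floor division, no padding."""

    def __init__(self, p: int):
        self.p = p

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        *lead, T = x.shape
        To = T // self.p
        self._in_T = T
        xr = x[..., : To * self.p].reshape(*lead, To, self.p)
        return xr.mean(axis=-1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        *lead, To = g.shape
        dx = np.zeros((*lead, self._in_T), dtype=F32)
        dx[..., : To * self.p] = np.repeat(g / self.p, self.p, axis=-1)
        return dx


class Dropout(Layer):
    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p == 0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training mode without an RNG")
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(_uniform(rng, n_in, (n_in, n_out)))
        self.b = Param(_uniform(rng, n_in, (n_out,)))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T


# ----------------------------------------------------------------------
def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class ChannelAttention(Layer):
    """CBAM-style channel gate: concat[GAP, GMP] -> 2C -> C -> C/2 -> C -> sigmoid.

    Gates are strictly in (0, 1) and multiply the feature maps channel-wise.
    """

    def __init__(self, C: int, rng: np.random.Generator):
        self.C = C
        self.fc1 = Dense(2 * C, C, rng)
        self.fc2 = Dense(C, C // 2, rng)
        self.fc3 = Dense(C // 2, C, rng)
        self.r1, self.r2 = ReLU(), ReLU()

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params() + self.fc3.params()

    def gates(self, x: np.ndarray, training: bool) -> np.ndarray:
        """Compute the per-map gate vector [B, C] for input [B, C, 1, T]."""
        xs = x[:, :, 0, :]
        self._T = xs.shape[2]
        avg = xs.mean(axis=2)
        self._amax = xs.argmax(axis=2)
        mx = np.take_along_axis(xs, self._amax[:, :, None], axis=2)[:, :, 0]
        z = np.concatenate([avg, mx], axis=1).astype(F32)
        h = self.r1.forward(self.fc1.forward(z, training), training)
        h = self.r2.forward(self.fc2.forward(h, training), training)
        self._logits = self.fc3.forward(h, training)
        return _sigmoid(self._logits).astype(F32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        self.gate = self.gates(x, training)
        return x * self.gate[:, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, gate = self._x, self.gate
        dgate = (g * x).sum(axis=(2, 3))
        dx = g * gate[:, :, None, None]
        dlog = dgate * gate * (1.0 - gate)
        dz = self.fc1.backward(self.r1.backward(
            self.fc2.backward(self.r2.backward(self.fc3.backward(dlog)))))
        C = self.C
        davg, dmax = dz[:, :C], dz[:, C:]
        dx += (davg / self._T)[:, :, None, None]
        scatter = np.zeros(x[:, :, 0, :].shape, dtype=F32)
        np.put_along_axis(scatter, self._amax[:, :, None], dmax[:, :, None], axis=2)
        dx += scatter[:, :, None, :]
        return dx
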