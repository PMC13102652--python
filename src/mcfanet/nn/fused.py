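"""Fast exact evaluation of the network's entry block.

The entry block is input-BN -> zero-pad -> Conv2d(1, k) to F1 maps -> BN ->
grouped Conv2d(D, 1) with depth multiplier.  Computed literally it
materializes a ``[B, F1, D, T]`` tensor that dominates the training cost.
Because the F1 temporal filters are shared across the D rows and the
depthwise stage contracts D immediately afterwards, the two convolutions
commute:

    sum_d W2[c,j,d] * conv_t(x[d], w1[c]) = conv_t(sum_d W2[c,j,d] x[d], w1[c])

so the D-contraction can run first (cheap matmul), followed by per-map
temporal convolutions on a ``[B, 2*F1, T]`` tensor.  Both batch norms are
per-map affine transforms; their batch statistics, and every quantity the
exact backward pass needs, are moments of the input that reduce to small
contractions with per-trial caches computed once per fit:

* ``G_i = col_i' col_i`` — the 64x64 Gram matrix of the trial's padded
  sliding windows (gives E[u^2] per temporal map);
* ``colsum_t`` — window sums over rows, [T, 64] (gives means and
  edge-profile cross terms);
* ``Xhat`` — the rFFT of the padded trial, used to form the
  gradient-input correlation R[m, d, k] = sum_{b,t} g[b,m,t] x[b,d,t+k]
  in the frequency domain.

The fused block *shares* the Param objects and running statistics of the
three reference layers, so reference and fused paths are interchangeable;
their agreement is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sfft

from .layers import F32, BatchNorm, SpatialDepthwiseConv, StandardizedTemporalConv

__all__ = ["FusedEntryBlock"]

C64 = np.complex64


class FusedEntryBlock:
    """Wraps (StandardizedTemporalConv, BatchNorm, SpatialDepthwiseConv)."""

    def __init__(self, conv: StandardizedTemporalConv, bn: BatchNorm,
                 dw: SpatialDepthwiseConv):
        self.conv, self.bn, self.dw = conv, bn, dw
        self.k = conv.k
        self.mult = dw.mult

    # ------------------------------------------------------------------
    def prepare_cache(self, X: np.ndarray) -> dict:
        """Per-trial moment caches for X of shape [N, 1, D, T] (training input)."""
        N, _, D, T = X.shape
        k, pl, pr = self.k, self.conv.pl, self.conv.pr
        Tin = T + pl + pr
        nfft = sfft.next_fast_len(Tin, real=True)
        gram = np.empty((N, k, k), dtype=F32)
        colsum_t = np.empty((N, T, k), dtype=F32)
        xhat = np.empty((N, D, nfft // 2 + 1), dtype=C64)
        sx = np.empty(N, dtype=np.float64)
        sx2 = np.empty(N, dtype=np.float64)
        xp = np.zeros((D, Tin), dtype=F32)
        for i in range(N):
            xp[:, pl : pl + T] = X[i, 0]
            win = sliding_window_view(xp, k, axis=1)  # [D, T, k] view
            colsum_t[i] = win.sum(axis=0)
            col = np.ascontiguousarray(win).reshape(-1, k)
            gram[i] = col.T @ col
            xhat[i] = sfft.rfft(xp, n=nfft, axis=1).astype(C64)
            sx[i] = float(X[i].sum(dtype=np.float64))
            sx2[i] = float((X[i].astype(np.float64) ** 2).sum())
        return {
            "gram": gram, "colsum_t": colsum_t, "xhat": xhat,
            "sx": sx, "sx2": sx2, "n_per_trial": D * T, "nfft": nfft,
        }

    @staticmethod
    def gather(cache: dict, idx: np.ndarray) -> dict:
        out = {key: cache[key][idx] for key in ("gram", "colsum_t", "xhat", "sx", "sx2")}
        out["n_per_trial"] = cache["n_per_trial"]
        out["nfft"] = cache["nfft"]
        return out

    # ------------------------------------------------------------------
    def _affines(self, x: np.ndarray, training: bool, aux: dict | None):
        """Input-BN scalars (a0, b0) and per-map BN1 affine (s, t)."""
        conv, bn = self.conv, self.bn
        B, _, D, T = x.shape
        W1 = conv.W.value  # [k, F1]
        E1t = conv._edge_profile(T)  # [T, F1]
        if not training:
            inv0 = 1.0 / np.sqrt(conv.running_var + conv.eps)
            a0 = float(conv.gamma.value[0]) * inv0
            b0 = float(conv.beta.value[0]) - a0 * conv.running_mean
            inv1 = 1.0 / np.sqrt(bn.running_var + bn.eps)
            s = bn.gamma.value * inv1
            t = bn.beta.value - s * bn.running_mean
            return a0, b0, s.astype(F32), t.astype(F32), E1t, None
        if aux is None:
            raise RuntimeError("training forward through the fused block needs the cache")
        n0 = B * x[0].size
        mu0 = float(aux["sx"].sum()) / n0
        var0 = float(aux["sx2"].sum()) / n0 - mu0 * mu0
        conv.running_mean = (1 - conv.momentum) * conv.running_mean + conv.momentum * mu0
        conv.running_var = (1 - conv.momentum) * conv.running_var \
            + conv.momentum * var0 * n0 / max(n0 - 1, 1)
        inv0 = 1.0 / np.sqrt(var0 + conv.eps)
        a0 = float(conv.gamma.value[0]) * inv0
        b0 = float(conv.beta.value[0]) - a0 * mu0
        # BN1 batch statistics of the (never materialized) conv output u
        nBDT = B * D * T
        Mb = aux["gram"].sum(axis=0, dtype=np.float64)  # [k, k]
        colsum_bt = aux["colsum_t"].sum(axis=0, dtype=np.float64)  # [T, k]
        colsum_k = colsum_bt.sum(axis=0)  # [k]
        W1d = W1.astype(np.float64)
        E1d = E1t.astype(np.float64)
        mu1 = (a0 * (colsum_k @ W1d) + b0 * B * D * E1d.sum(axis=0)) / nBDT  # [F1]
        MW = Mb @ W1d  # [k, F1]
        eu2 = (
            a0 * a0 * np.einsum("kc,kc->c", W1d, MW)
            + 2 * a0 * b0 * np.einsum("tc,tc->c", E1d, colsum_bt @ W1d)
            + b0 * b0 * B * D * (E1d ** 2).sum(axis=0)
        ) / nBDT
        var1 = np.maximum(eu2 - mu1 ** 2, 0.0)
        bn.running_mean = ((1 - bn.momentum) * bn.running_mean
                           + bn.momentum * mu1).astype(F32)
        bn.running_var = ((1 - bn.momentum) * bn.running_var
                          + bn.momentum * var1 * nBDT / max(nBDT - 1, 1)).astype(F32)
        sig1 = np.sqrt(var1 + bn.eps)
        s = bn.gamma.value / sig1
        t = bn.beta.value - s * mu1
        stats = {
            "mu0": mu0, "inv0": inv0, "mu1": mu1, "sig1": sig1,
            "Mb": Mb, "colsum_bt": colsum_bt, "colsum_k": colsum_k,
            "nBDT": nBDT, "BD": B * D,
        }
        return a0, b0, s.astype(F32), t.astype(F32), E1t, stats

    def forward(self, x: np.ndarray, training: bool, aux: dict | None = None
                ) -> np.ndarray:
        B, _, D, T = x.shape
        k, pl, pr = self.k, self.conv.pl, self.conv.pr
        a0, b0, s, t, E1t, stats = self._affines(x, training, aux)
        F1 = self.conv.W.value.shape[1]
        M = F1 * self.mult
        # depthwise contraction first: y[b, m, t'] = sum_d W2[m, d] x_pad[b, d, t']
        W2f = self.dw.W.value.reshape(M, D)
        xp = np.zeros((B, D, T + pl + pr), dtype=F32)
        xp[:, :, pl : pl + T] = x[:, 0]
        y = np.matmul(W2f[None], xp)  # [B, M, Tin]
        # per-map temporal cross-correlation with the (repeated) F1 kernels,
        # done in the frequency domain
        Wm = np.repeat(self.conv.W.value.T, self.mult, axis=0)  # [M, k]
        nfft = sfft.next_fast_len(y.shape[2], real=True)
        Yh = sfft.rfft(y, n=nfft, axis=2)
        Wh = np.conj(sfft.rfft(Wm, n=nfft, axis=1))
        z = sfft.irfft(Yh * Wh[None], n=nfft, axis=2)[:, :, :T].astype(F32)
        s_m = np.repeat(s, self.mult)
        t_m = np.repeat(t, self.mult)
        W2s = self.dw.W.value.sum(axis=2).reshape(M)  # sum over d, [M]
        E1m = np.repeat(E1t.T, self.mult, axis=0)  # [M, T]
        z *= (a0 * s_m)[None, :, None]
        z += ((b0 * s_m * W2s)[:, None] * E1m + (t_m * W2s)[:, None])[None]
        self._ctx = {
            "a0": a0, "b0": b0, "s": s, "t": t, "E1t": E1t,
            "stats": stats, "B": B, "D": D, "T": T, "aux": aux,
        }
        return z[:, :, None, :]

    # ------------------------------------------------------------------
    def backward(self, gz: np.ndarray) -> None:
        """Exact parameter gradients; training mode only (no input gradient)."""
        ctx = self._ctx
        stats, aux = ctx["stats"], ctx["aux"]
        if stats is None:
            raise RuntimeError("fused backward is only defined after a training forward")
        a0, b0 = ctx["a0"], ctx["b0"]
        B, D, T = ctx["B"], ctx["D"], ctx["T"]
        k = self.k
        F1 = self.conv.W.value.shape[1]
        mult = self.mult
        Mmaps = F1 * mult
        W1 = self.conv.W.value.astype(np.float64)  # [k, F1]
        W2 = self.dw.W.value.astype(np.float64)  # [F1, mult, D]
        W2s = W2.sum(axis=2)  # [F1, mult]
        E1 = ctx["E1t"].astype(np.float64)  # [T, F1]
        s = ctx["s"].astype(np.float64)
        t = ctx["t"].astype(np.float64)
        sig1, mu1 = stats["sig1"], stats["mu1"]
        nBDT, BD = stats["nBDT"], stats["BD"]

        gzs = gz[:, :, 0, :]  # [B, M, T]
        gzsum_ct = gzs.sum(axis=0, dtype=np.float64)  # [M, T]
        gzsum = gzsum_ct.sum(axis=1)  # [M]
        # GE[m] = sum_{b,t} gz[b,m,t] E1[c(m),t]
        E1m = np.repeat(E1.T, mult, axis=0)  # [M, T]
        GE = (gzsum_ct * E1m).sum(axis=1)  # [M]

        # R[m, d, k'] = sum_{b,t} gz[b,m,t] x_pad[b,d,t+k'] via rFFT
        nfft = aux["nfft"]
        Ghat = sfft.rfft(gzs.astype(F32), n=nfft, axis=2).astype(C64)
        V1 = np.ascontiguousarray(np.conj(Ghat).transpose(2, 1, 0))  # [F, M, B]
        V2 = np.ascontiguousarray(aux["xhat"].transpose(2, 0, 1))  # [F, B, D]
        Rhat = np.matmul(V1, V2).transpose(1, 2, 0)  # [M, D, F]
        R = sfft.irfft(Rhat.astype(np.complex128), n=nfft, axis=2)[:, :, :k]  # [M, D, k]
        Rr = R.reshape(F1, mult, D, k)

        # A1[c, k'] = sum_{j,d} W2[c,j,d] R[(c,j),d,k']
        A1 = np.einsum("cjd,cjdk->ck", W2, Rr)
        gzsum_r = gzsum.reshape(F1, mult)
        GEr = GE.reshape(F1, mult)

        # BN1 backward reduction scalars
        m1 = (W2s * gzsum_r).sum(axis=1) / nBDT  # [F1]
        sum_gv_u = a0 * np.einsum("kc,ck->c", W1, A1) + b0 * (W2s * GEr).sum(axis=1)
        m2 = (sum_gv_u / nBDT - mu1 * m1) / sig1
        self.bn.gamma.grad += (nBDT * m2).astype(F32)
        self.bn.beta.grad += (nBDT * m1).astype(F32)

        # dW2[c,j,d] = s_c * (a0 * sum_k W1[k,c] R[c,j,d,k] + b0 GE) + t_c gzsum
        dW2 = a0 * np.einsum("kc,cjdk->cjd", W1, Rr)
        dW2 += (b0 * GEr)[:, :, None]
        dW2 *= s[:, None, None]
        dW2 += (t[:, None] * gzsum_r)[:, :, None]
        self.dw.W.grad += dW2.astype(F32)

        # dW1 via gu = s (gv - m1 - uhat m2)
        colsum_bt, colsum_k, Mb = stats["colsum_bt"], stats["colsum_k"], stats["Mb"]
        Su_x = a0 * (W1.T @ Mb) + b0 * (E1.T @ colsum_bt)  # [F1, k]
        A2 = (Su_x - mu1[:, None] * colsum_k[None]) / sig1[:, None]
        Sgux = s[:, None] * (A1 - m1[:, None] * colsum_k[None] - m2[:, None] * A2)
        # E1-path pieces
        gvsum_ct = np.einsum("cj,cjt->ct", W2s, gzsum_ct.reshape(F1, mult, T))
        usum_ct = a0 * (colsum_bt @ W1).T + b0 * BD * E1.T  # [F1, T]
        uhsum_ct = (usum_ct - BD * mu1[:, None]) / sig1[:, None]
        gusum_ct = s[:, None] * (gvsum_ct - BD * m1[:, None] - m2[:, None] * uhsum_ct)
        pcol = self.conv._pcol.astype(np.float64)  # [T, k]
        dW1 = a0 * Sgux.T + b0 * (pcol.T @ gusum_ct.T)  # [k, F1]
        self.conv.W.grad += dW1.astype(F32)

        # input-BN gradients through a0, b0
        dLda0 = float(np.einsum("kc,ck->", W1, Sgux))
        dLdb0 = float((E1.T * gusum_ct).sum())
        mu0, inv0 = stats["mu0"], stats["inv0"]
        self.conv.gamma.grad[0] += F32((dLda0 - dLdb0 * mu0) * inv0)
        self.conv.beta.grad[0] += F32(dLdb0)
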