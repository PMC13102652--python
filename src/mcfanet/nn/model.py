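"""The MCFANet backbone: temporal conv, depthwise virtual-channel conv,
separable temporal conv, channel attention, dense classifier.

Layer sequence on input ``[B, 1, D, T]``:

* input batch norm (single map), zero-pad time (32, 31), Conv2d (1, 64) to
  F1 = 16 temporal maps, batch norm;
* grouped Conv2d (D, 1) with F1 groups and depth multiplier 2 ->
  2*F1 = 32 maps, batch norm, ELU, AvgPool (1, 4), dropout;
* zero-pad time (7, 8), grouped Conv2d (1, 16) depthwise, pointwise
  Conv2d (1, 1) to F2 = 32, batch norm, ELU, AvgPool (1, 8), dropout;
* channel attention (concat[GAP, GMP] -> 64 -> 32 -> 16 -> 32 -> sigmoid);
* flatten (32 * T//32), dense 128 + batch norm + ReLU + dropout, dense K.

Pooling uses floor division without padding, so time lengths follow
``T -> T//4 -> T//32`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    F32,
    AvgPoolTime,
    BatchNorm,
    ChannelAttention,
    Dense,
    Dropout,
    ELU,
    Flatten,
    Layer,
    PointwiseConv,
    ReLU,
    SpatialDepthwiseConv,
    StandardizedTemporalConv,
    TemporalDepthwiseConv,
)

__all__ = ["NetConfig", "MCFANetBackbone", "build_mcfanet", "count_parameters"]


@dataclass
class NetConfig:
    """Architecture hyperparameters (defaults follow the reference layout)."""

    n_classes: int = 4
    F1: int = 16
    depth_multiplier: int = 2
    F2: int = 32
    temporal_kernel: int = 64
    separable_kernel: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.5
    hidden: int = 128

    def __post_init__(self) -> None:
        if self.F2 != self.F1 * self.depth_multiplier:
            raise ValueError(
                f"F2 ({self.F2}) must equal F1 * depth_multiplier "
                f"({self.F1} * {self.depth_multiplier})"
            )
        for name in ("temporal_kernel", "separable_kernel", "pool1", "pool2"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


class MCFANetBackbone:
    """The network, its parameters, and explicit forward/backward passes.

    Two interchangeable execution paths exist for the entry block
    (input BN + temporal conv + BN + depthwise): a literal layer-by-layer
    ``reference`` path and a mathematically equivalent ``fused`` path that
    avoids materializing the ``[B, F1, D, T]`` intermediate (see
    ``nn.fused``).  They share parameters and running statistics; the fused
    path is the default for training and prediction, the reference path
    backs the input-gradient (interpretability) computation and serves as
    the oracle in equivalence tests.
    """

    def __init__(self, D: int, T: int, cfg: NetConfig | None = None, seed: int = 0,
                 engine: str = "fused"):
        cfg = cfg or NetConfig()
        if T < cfg.temporal_kernel:
            raise ValueError(
                f"trial length T={T} is shorter than the temporal kernel "
                f"({cfg.temporal_kernel} samples)"
            )
        if D < 1:
            raise ValueError("need at least one input channel")
        self.D, self.T, self.cfg = D, T, cfg
        rng = np.random.default_rng(seed)
        C2 = cfg.F2
        self.t_out = (T // cfg.pool1) // cfg.pool2
        self.flat_width = C2 * self.t_out
        self.block0 = StandardizedTemporalConv(cfg.F1, cfg.temporal_kernel, rng)
        self.embed_relu = ReLU()
        self.layers: list[Layer] = [
            self.block0,
            BatchNorm(cfg.F1),
            SpatialDepthwiseConv(cfg.F1, D, cfg.depth_multiplier, rng),
            BatchNorm(C2),
            ELU(),
            AvgPoolTime(cfg.pool1),
            Dropout(cfg.dropout),
            TemporalDepthwiseConv(C2, cfg.separable_kernel, rng),
            PointwiseConv(C2, C2, rng),
            BatchNorm(C2),
            ELU(),
            AvgPoolTime(cfg.pool2),
            Dropout(cfg.dropout),
            ChannelAttention(C2, rng),
            Flatten(),
            Dense(self.flat_width, cfg.hidden, rng),
            BatchNorm(cfg.hidden),
            self.embed_relu,
            Dropout(cfg.dropout),
            Dense(cfg.hidden, cfg.n_classes, rng),
        ]
        if engine not in ("fused", "reference"):
            raise ValueError(f"unknown engine '{engine}'")
        self.engine = engine
        from .fused import FusedEntryBlock

        self.fused = FusedEntryBlock(self.block0, self.layers[1], self.layers[2])

    # ------------------------------------------------------------------
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def set_rng(self, rng: np.random.Generator) -> None:
        """Attach the RNG that drives dropout masks during training."""
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # ------------------------------------------------------------------
    @staticmethod
    def as_input(X: np.ndarray) -> np.ndarray:
        """[N, D, T] float array -> [N, 1, D, T] float32."""
        X = np.asarray(X, dtype=F32)
        if X.ndim == 3:
            X = X[:, None]
        return X

    def prepare_cache(self, X: np.ndarray):
        """Per-trial caches reused across epochs during a fit."""
        if self.engine == "fused":
            return self.fused.prepare_cache(X)
        return self.block0._pad_cols(X).reshape(X.shape[0], -1, self.block0.k)

    def gather_aux(self, cache, idx: np.ndarray):
        if self.engine == "fused":
            return self.fused.gather(cache, idx)
        return np.ascontiguousarray(cache[idx]).reshape(-1, self.block0.k)

    def forward(self, x: np.ndarray, training: bool, aux=None,
                engine: str | None = None) -> np.ndarray:
        engine = engine or self.engine
        self._last_engine = engine
        if engine == "fused":
            out = self.fused.forward(x, training, aux=aux)
            start = 3
        else:
            out = self.block0.forward(x, training, col=aux)
            for layer in self.layers[1:3]:
                out = layer.forward(out, training)
            start = 3
        for layer in self.layers[start:]:
            out = layer.forward(out, training)
        return out

    def backward(self, g: np.ndarray, need_input_grad: bool = False):
        for layer in reversed(self.layers[3:]):
            g = layer.backward(g)
        if self._last_engine == "fused":
            if need_input_grad:
                raise RuntimeError("input gradients require the reference engine")
            return self.fused.backward(g)
        for layer in reversed(self.layers[1:3]):
            g = layer.backward(g)
        return self.block0.backward(g, need_dx=need_input_grad)

    # ------------------------------------------------------------------
    def predict_logits(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Deterministic eval-mode forward over a dataset [N, D, T]."""
        X = self.as_input(X)
        outs = [self.forward(X[i : i + batch_size], training=False)
                for i in range(0, X.shape[0], batch_size)]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        logits = self.predict_logits(X, batch_size)
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_logits(X, batch_size).argmax(axis=1)

    def embeddings(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Penultimate-layer activations (post-ReLU, dropout off), [N, hidden]."""
        X = self.as_input(X)
        outs = []
        for i in range(0, X.shape[0], batch_size):
            self.forward(X[i : i + batch_size], training=False)
            outs.append(self.embed_relu.out.copy())
        return np.concatenate(outs, axis=0)

    def input_gradients(self, X: np.ndarray, targets: np.ndarray,
                        batch_size: int = 16) -> np.ndarray:
        """d(logit of target class)/d(input), eval mode; [N, D, T]."""
        X = self.as_input(X)
        targets = np.asarray(targets)
        grads = []
        for i in range(0, X.shape[0], batch_size):
            xb, yb = X[i : i + batch_size], targets[i : i + batch_size]
            logits = self.forward(xb, training=False, engine="reference")
            g = np.zeros_like(logits)
            g[np.arange(len(yb)), yb] = 1.0
            dx = self.backward(g, need_input_grad=True)
            grads.append(dx[:, 0].copy())
        self.zero_grad()  # discard parameter grads accumulated along the way
        return np.concatenate(grads, axis=0)


    # ------------------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        """All trainable parameters and normalization running statistics."""
        out = {f"param{i}": p.value for i, p in enumerate(self.params())}
        out["bn0_running"] = np.array(
            [self.block0.running_mean, self.block0.running_var])
        j = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                out[f"bn{j}_mean"] = layer.running_mean
                out[f"bn{j}_var"] = layer.running_var
                j += 1
        return out

    def load_state_arrays(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            val = np.asarray(state[f"param{i}"], dtype=F32)
            if val.shape != p.value.shape:
                raise ValueError(f"param{i} shape {val.shape} != {p.value.shape}")
            p.value = val
            p.grad = np.zeros_like(val)
        self.block0.running_mean = float(state["bn0_running"][0])
        self.block0.running_var = float(state["bn0_running"][1])
        j = 0
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(state[f"bn{j}_mean"], dtype=F32)
                layer.running_var = np.asarray(state[f"bn{j}_var"], dtype=F32)
                j += 1


def build_mcfanet(D: int, T: int, cfg: NetConfig | None = None, seed: int = 0
                  ) -> MCFANetBackbone:
    """Build the backbone for D virtual channels and T samples."""
    return MCFANetBackbone(D, T, cfg, seed)


def count_parameters(model: MCFANetBackbone) -> int:
    """Total trainable scalar count."""
    return int(sum(p.value.size for p in model.params()))
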