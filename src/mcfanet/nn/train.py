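"""Adam optimization of the backbone on softmax cross-entropy.

Training follows the evaluation protocol's settings: learning rate 0.001,
batch size 32, Adam, cross-entropy, with all hyperparameters fixed across
subjects and folds.  Batches are reshuffled every epoch with the run seed;
the last partial batch is kept (drop-last disabled).  The number of epochs
is a free parameter (default 300, no early stopping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import F32, Param
from .model import MCFANetBackbone

__all__ = ["TrainConfig", "Adam", "cross_entropy_loss", "train_model"]


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 300
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("learning rate must be non-negative")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Param], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.beta1 ** self.t
        b2t = 1.0 - c.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= c.beta1
            m += (1 - c.beta1) * p.grad
            v *= c.beta2
            v += (1 - c.beta2) * p.grad ** 2
            p.value -= F32(c.lr) * (m / b1t) / (np.sqrt(v / b2t) + c.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray]:
    """Mean negative log softmax-probability of the true class.

    Returns ``(loss, dlogits)`` with the gradient already averaged over the
    batch: ``dlogits = (softmax(logits) - onehot) / B``.
    """
    logits = np.asarray(logits)
    labels = np.asarray(labels)
    B, K = logits.shape
    if labels.shape != (B,):
        raise ValueError(f"labels shape {labels.shape} does not match batch {B}")
    if labels.size and (labels.min() < 0 or labels.max() >= K):
        raise ValueError(f"labels must lie in 0..{K - 1}")
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.maximum(p[np.arange(B), labels], 1e-300)).mean())
    dlogits = p.astype(F32)
    dlogits[np.arange(B), labels] -= 1.0
    dlogits /= F32(B)
    return loss, dlogits


def train_model(model: MCFANetBackbone, X: np.ndarray, y: np.ndarray,
                cfg: TrainConfig | None = None) -> list[float]:
    """Train in place; returns the per-epoch mean loss trajectory.

    The im2col matrix of the (fixed) input is computed once per fit and
    re-gathered per batch, which removes the dominant cost of the first
    convolution from the inner loop.

    Raises
    ------
    FloatingPointError
        If the loss becomes non-finite (divergence).
    """
    cfg = cfg or TrainConfig()
    X = model.as_input(X)
    y = np.asarray(y, dtype=np.int64)
    n = X.shape[0]
    if y.shape != (n,):
        raise ValueError("labels must match the number of trials")
    rng = np.random.default_rng(cfg.seed)
    model.set_rng(rng)
    opt = Adam(model.params(), cfg)
    cache = model.prepare_cache(X)  # per-trial moments, reused every epoch
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = X[idx]
            model.zero_grad()
            logits = model.forward(xb, training=True, aux=model.gather_aux(cache, idx))
            loss, dlogits = cross_entropy_loss(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: loss={loss} at step {opt.t}"
                )
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history
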