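"""Reported statistics and interpretability analyses.

* per-class and macro F1;
* paired t-test with Cohen's d (paired standardizer mean(diff)/sd(diff));
* gradient-based virtual-channel importance, aggregated by frequency
  sub-band and by CSP filter class;
* Welch band-power raw features (the C x F "raw feature" representation);
* deep-embedding export from the penultimate dense layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, signal, stats as sps
from sklearn.metrics import f1_score

from .csp import VirtualChannelSet
from .epochs import EpochSet
from .filterbank import BandSpec
from .nn.model import MCFANetBackbone

__all__ = [
    "macro_f1",
    "PairedStats",
    "paired_stats",
    "ImportanceMap",
    "gradient_importance",
    "welch_bandpower_features",
    "export_embeddings",
]


def macro_f1(y_true, y_pred) -> tuple[np.ndarray, float]:
    """Per-class F1 (harmonic mean of precision and recall) and their mean.

    Classes are those present in ``y_true``; a class never predicted gets
    F1 = 0 by the zero-division convention.  A class present in the
    predictions but absent from ``y_true`` has undefined recall and raises.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = np.unique(y_true)
    missing = np.setdiff1d(np.unique(y_pred), classes)
    if missing.size:
        raise ValueError(
            f"classes {missing.tolist()} appear in predictions but not in "
            "y_true; their recall is undefined"
        )
    per_class = f1_score(y_true, y_pred, average=None, labels=classes,
                         zero_division=0)
    return per_class, float(per_class.mean())


@dataclass(frozen=True)
class PairedStats:
    t: float
    p: float
    d: float
    df: int


def paired_stats(a, b) -> PairedStats:
    """Paired-samples t-test and Cohen's d for matched accuracy vectors.

    ``t = mean(diff) / (sd(diff) / sqrt(n))`` with sd using n-1;
    ``d = mean(diff) / sd(diff)``; two-sided p from the t distribution with
    n-1 degrees of freedom.  Identical vectors (zero-variance differences)
    are an error — the statistic is undefined, not zero.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: paired t is undefined")
    n = diff.size
    d = float(diff.mean() / sd)
    t = float(d * np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return PairedStats(t=t, p=p, d=d, df=n - 1)


# ----------------------------------------------------------------------
@dataclass
class ImportanceMap:
    """Gradient-based input importance, aggregated over the channel map.

    ``channel_scores[d]`` is the absolute gradient of the true-class logit
    w.r.t. virtual channel d, averaged over time and trials (>= 0).
    ``band_percent`` (length F) and ``class_band_percent`` (K x F) are
    normalized to sum to 100 within the subject.
    """

    channel_scores: np.ndarray
    band_percent: np.ndarray
    class_band_percent: np.ndarray
    index_map: list

    def __post_init__(self) -> None:
        if (self.channel_scores < 0).any():
            raise ValueError("importance scores must be non-negative")


def gradient_importance(net: MCFANetBackbone, vc: VirtualChannelSet
                        ) -> ImportanceMap:
    """Saliency of each virtual channel for the network's decision.

    Per trial, the gradient of the true-class logit w.r.t. the input is
    taken in eval mode; its absolute value is averaged over time, then over
    trials, and aggregated through the (class, band, component) index map.
    """
    if not vc.index_map:
        raise ValueError("virtual-channel set lacks an index map")
    grads = net.input_gradients(vc.data.astype(np.float32), vc.labels)
    scores = np.abs(grads).mean(axis=2).mean(axis=0)  # [D]
    ks = np.array([k for (k, f, c) in vc.index_map])
    fs_ = np.array([f for (k, f, c) in vc.index_map])
    K, F = ks.max() + 1, fs_.max() + 1
    band = np.zeros(F)
    grid = np.zeros((K, F))
    for d, (k, f, _c) in enumerate(vc.index_map):
        band[f] += scores[d]
        grid[k, f] += scores[d]
    band = 100.0 * band / band.sum()
    grid = 100.0 * grid / grid.sum()
    return ImportanceMap(channel_scores=scores, band_percent=band,
                         class_band_percent=grid, index_map=list(vc.index_map))


# ----------------------------------------------------------------------
def welch_bandpower_features(epochs: EpochSet, bands: list[BandSpec],
                             seg_seconds: float = 1.0) -> np.ndarray:
    """Welch band power per channel and sub-band, flattened to [n, C*F].

    The PSD uses Hann-windowed segments of ``seg_seconds`` with 50% overlap;
    band power integrates the spectrum over the band-interior frequency
    bins by the trapezoid rule.  Feature order is channel-major: the F band
    powers of channel 0, then channel 1, ...
    """
    for band in bands:
        if band.high_hz >= epochs.fs / 2:
            raise ValueError(f"band {band} reaches the Nyquist frequency")
    nperseg = min(int(round(seg_seconds * epochs.fs)), epochs.n_samples)
    freqs, psd = signal.welch(
        epochs.data, fs=epochs.fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, axis=-1,
    )
    feats = np.empty((epochs.n_trials, epochs.n_channels, len(bands)))
    for j, band in enumerate(bands):
        sel = (freqs >= band.low_hz) & (freqs <= band.high_hz)
        if sel.sum() < 2:
            raise ValueError(f"band {band} covers fewer than two Welch bins")
        feats[:, :, j] = integrate.trapezoid(psd[..., sel], freqs[sel], axis=-1)
    return feats.reshape(epochs.n_trials, -1)


def export_embeddings(net: MCFANetBackbone, vc: VirtualChannelSet) -> np.ndarray:
    """Penultimate-layer activations (post-ReLU, dropout off), [n, hidden]."""
    import warnings

    if net.cfg.hidden != 128:
        warnings.warn(
            f"embedding width is {net.cfg.hidden}, not the conventional 128",
            stacklevel=2,
        )
    return net.embeddings(vc.data.astype(np.float32))
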