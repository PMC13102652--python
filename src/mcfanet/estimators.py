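"""Scikit-learn style estimators for the decoding pipelines.

All estimators consume ``X`` of shape ``[n_trials, n_channels, n_samples]``
and integer labels ``y``; they follow the sklearn contract (``get_params``
/ ``set_params`` / ``clone``-compatible ``__init__``, fitted attributes
with trailing underscores) so they compose with sklearn model selection.

* :class:`MCFANetClassifier` — the full method: filter bank, one-vs-rest
  CSP per (class, band), virtual-channel fusion, attention CNN.
* :class:`FBEEGNetClassifier` — ablation: a *single* class's CSP filter
  set (D' = F * 2m virtual channels) feeding the same backbone.
* :class:`FBCSPClassifier` — classic pipeline: one-vs-rest CSP per band,
  log-variance features, shrinkage LDA.
* :class:`CSPClassifier` — the same on a single broadband 8-32 Hz filter.
* :class:`BackboneRawClassifier` — the CNN on raw channels (no CSP).

Leakage control is structural: ``fit`` sees only the training trials, and
every data-dependent stage (band-pass statistics are stateless; CSP filters;
network weights) lives on the fitted estimator.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .csp import (
    SpatialFilterBank,
    fit_ovr_csp,
    fuse_virtual_channels,
    logvar_features,
)
from .epochs import EpochSet
from .filterbank import BandEpochs, apply_filterbank, make_bands
from .nn import NetConfig, TrainConfig, build_mcfanet, train_model

__all__ = [
    "MCFANetClassifier",
    "FBEEGNetClassifier",
    "FBCSPClassifier",
    "CSPClassifier",
    "BackboneRawClassifier",
]


class _FilterBankMixin:
    """Shared band decomposition for array inputs."""

    def _bands(self):
        return make_bands(self.band_low, self.band_high, self.band_width)

    def _band_epochs(self, X: np.ndarray, y: np.ndarray | None) -> BandEpochs:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(f"X must be [trials, channels, samples], got {X.shape}")
        y = np.zeros(X.shape[0], dtype=np.int64) if y is None else np.asarray(y)
        ep = EpochSet(data=X, labels=np.zeros(X.shape[0], dtype=np.int64), fs=self.fs)
        be = apply_filterbank(ep, self._bands(), order=self.filter_order,
                              family=self.filter_family)
        be.labels = y
        return be

    def _encode(self, y: np.ndarray) -> np.ndarray:
        self.classes_ = np.unique(y)
        lut = {c: i for i, c in enumerate(self.classes_)}
        return np.array([lut[v] for v in y], dtype=np.int64)


class _BackboneClassifier(BaseEstimator, ClassifierMixin, _FilterBankMixin):
    """Common training/prediction machinery for the CNN-based estimators."""

    def _net_config(self, n_classes: int) -> NetConfig:
        return NetConfig(n_classes=n_classes, dropout=self.dropout,
                         hidden=self.hidden)

    def _fit_net(self, V: np.ndarray, y_enc: np.ndarray) -> None:
        n_classes = len(self.classes_)
        self.net_ = build_mcfanet(V.shape[1], V.shape[2],
                                  self._net_config(n_classes), seed=self.seed)
        self.history_ = train_model(
            self.net_, V.astype(np.float32), y_enc,
            TrainConfig(lr=self.lr, batch_size=self.batch_size,
                        epochs=self.epochs, seed=self.seed),
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.net_.predict(self._representation(X))]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net_.predict_proba(self._representation(X))

    def embeddings(self, X: np.ndarray) -> np.ndarray:
        """Penultimate-layer (128-d by default) embeddings, one row per trial."""
        return self.net_.embeddings(self._representation(X))


class MCFANetClassifier(_BackboneClassifier):
    """Filter-bank one-vs-rest CSP fusion + attention CNN.

    Parameters
    ----------
    m : int
        CSP filter pairs per (class, band); the fused representation has
        D = K * F * 2m virtual channels.  Requires 2m <= n_channels.
    epochs, lr, batch_size, seed : training settings (Adam, cross-entropy).
    """

    def __init__(self, m: int = 1, band_low: float = 8.0, band_high: float = 32.0,
                 band_width: float = 4.0, filter_order: int = 4,
                 filter_family: str = "butter", fs: float = 250.0,
                 ridge: float = 1e-8, epochs: int = 100, lr: float = 1e-3,
                 batch_size: int = 32, dropout: float = 0.5, hidden: int = 128,
                 seed: int = 0):
        self.m = m
        self.band_low = band_low
        self.band_high = band_high
        self.band_width = band_width
        self.filter_order = filter_order
        self.filter_family = filter_family
        self.fs = fs
        self.ridge = ridge
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.dropout = dropout
        self.hidden = hidden
        self.seed = seed

    def _select_filters(self, bank: SpatialFilterBank) -> SpatialFilterBank:
        return bank

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MCFANetClassifier":
        y_enc = self._encode(np.asarray(y))
        be = self._band_epochs(X, y_enc)
        self.filters_ = self._select_filters(
            fit_ovr_csp(be, m=self.m, ridge=self.ridge))
        vc = fuse_virtual_channels(be, self.filters_)
        self.index_map_ = list(vc.index_map)
        self._fit_net(vc.data, y_enc)
        return self

    def virtual_channels(self, X: np.ndarray, y: np.ndarray | None = None):
        """Fused virtual-channel representation under the fitted filters."""
        be = self._band_epochs(X, y)
        return fuse_virtual_channels(be, self.filters_)

    def _representation(self, X: np.ndarray) -> np.ndarray:
        return self.virtual_channels(X).data


class FBEEGNetClassifier(MCFANetClassifier):
    """Ablation baseline: one class's CSP filter set only (D' = F * 2m).

    ``reference_class`` selects which one-vs-rest binary problem provides
    the filters (the choice the fused method deliberately avoids making).
    """

    def __init__(self, m: int = 1, reference_class: int = 0, band_low: float = 8.0,
                 band_high: float = 32.0, band_width: float = 4.0,
                 filter_order: int = 4, filter_family: str = "butter",
                 fs: float = 250.0, ridge: float = 1e-8, epochs: int = 100,
                 lr: float = 1e-3, batch_size: int = 32, dropout: float = 0.5,
                 hidden: int = 128, seed: int = 0):
        super().__init__(m=m, band_low=band_low, band_high=band_high,
                         band_width=band_width, filter_order=filter_order,
                         filter_family=filter_family, fs=fs, ridge=ridge,
                         epochs=epochs, lr=lr, batch_size=batch_size,
                         dropout=dropout, hidden=hidden, seed=seed)
        self.reference_class = reference_class

    def _select_filters(self, bank: SpatialFilterBank) -> SpatialFilterBank:
        k = self.reference_class
        if not 0 <= k < bank.n_classes:
            raise ValueError(f"reference_class {k} out of range")
        return SpatialFilterBank(
            W=[bank.W[k]], eigenvalues=bank.eigenvalues[k : k + 1],
            m=bank.m, class_names=[bank.class_names[k]] if bank.class_names else [],
            bands=bank.bands,
        )


class FBCSPClassifier(BaseEstimator, ClassifierMixin, _FilterBankMixin):
    """Filter-bank CSP with log-variance features and shrinkage LDA."""

    def __init__(self, m: int = 2, band_low: float = 8.0, band_high: float = 32.0,
                 band_width: float = 4.0, filter_order: int = 4,
                 filter_family: str = "butter", fs: float = 250.0,
                 ridge: float = 1e-8):
        self.m = m
        self.band_low = band_low
        self.band_high = band_high
        self.band_width = band_width
        self.filter_order = filter_order
        self.filter_family = filter_family
        self.fs = fs
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FBCSPClassifier":
        y_enc = self._encode(np.asarray(y))
        be = self._band_epochs(X, y_enc)
        self.filters_ = fit_ovr_csp(be, m=self.m, ridge=self.ridge)
        feats = self._features(be)
        self.lda_ = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        self.lda_.fit(feats, y_enc)
        return self

    def _features(self, be: BandEpochs) -> np.ndarray:
        return logvar_features(fuse_virtual_channels(be, self.filters_))

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Log-variance feature matrix [n_trials, K * F * 2m]."""
        return self._features(self._band_epochs(X, None))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.lda_.predict(self.transform(X))]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.lda_.predict_proba(self.transform(X))


class CSPClassifier(FBCSPClassifier):
    """Broadband (8-32 Hz) one-vs-rest CSP + log-variance + LDA."""

    def __init__(self, m: int = 2, band_low: float = 8.0, band_high: float = 32.0,
                 filter_order: int = 4, filter_family: str = "butter",
                 fs: float = 250.0, ridge: float = 1e-8):
        super().__init__(m=m, band_low=band_low, band_high=band_high,
                         band_width=band_high - band_low,
                         filter_order=filter_order, filter_family=filter_family,
                         fs=fs, ridge=ridge)


class BackboneRawClassifier(_BackboneClassifier):
    """The CNN backbone applied directly to raw channels (no CSP)."""

    def __init__(self, fs: float = 250.0, epochs: int = 100, lr: float = 1e-3,
                 batch_size: int = 32, dropout: float = 0.5, hidden: int = 128,
                 seed: int = 0):
        self.fs = fs
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.dropout = dropout
        self.hidden = hidden
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BackboneRawClassifier":
        y_enc = self._encode(np.asarray(y))
        X = np.asarray(X, dtype=np.float64)
        self._fit_net(X, y_enc)
        return self

    def _representation(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64)
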