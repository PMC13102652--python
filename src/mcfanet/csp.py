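"""Common Spatial Pattern filtering and multi-class virtual-channel fusion.

Binary CSP finds spatial filters w maximizing the class variance ratio

    J(w) = (w' S_i w) / (w' S_j w),

solved as the generalized eigenproblem ``S_i w = lambda S_j w``.  Large
eigenvalues give directions of high class-i / low class-j variance and
vice versa; the eigenvectors of the m largest and m smallest eigenvalues
form the projection matrix W in R^{C x 2m}.

The K-class extension trains K one-vs-rest binary problems per sub-band
(class k against the pooled remainder), yielding a projection W_k^{(f)} per
(class, band) pair.  Applying all projections to a trial and concatenating
the projected *time series* along the channel axis yields the virtual
channel representation V_n in R^{D x T} with D = K * F * 2m, ordered
class-major, then band, then component.  Unlike classic FBCSP, no
log-variance compression happens here; the full time courses are preserved
so a downstream network can exploit temporal dynamics.  Log-variance
features are provided separately for the FBCSP/CSP baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .filterbank import BandEpochs, BandSpec

__all__ = [
    "SpatialFilterBank",
    "VirtualChannelSet",
    "trial_covariance",
    "class_covariances",
    "solve_csp",
    "fit_ovr_csp",
    "fuse_virtual_channels",
    "logvar_features",
]


@dataclass
class SpatialFilterBank:
    """One-vs-rest CSP projections per (class, band).

    ``W[k][f]`` is a ``C x 2m`` projection whose columns are generalized
    eigenvectors, ordered m largest eigenvalues descending then m smallest
    ascending, each sign-normalized so its largest-magnitude coefficient is
    positive.  ``eigenvalues[k, f]`` stores the matching lambda values.
    """

    W: list[list[np.ndarray]]
    eigenvalues: np.ndarray  # [K, F, 2m]
    m: int
    class_names: list[str] = field(default_factory=list)
    bands: list[BandSpec] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.W)

    @property
    def n_bands(self) -> int:
        return len(self.W[0])

    @property
    def n_channels(self) -> int:
        return self.W[0][0].shape[0]


@dataclass
class VirtualChannelSet:
    """Fused CSP-projected time series ``[n_trials, D, n_samples]``.

    ``index_map[d] = (class k, band f, component c)`` identifies the origin
    of virtual channel ``d``; the layout is class-major, then band, then
    component, so channels 0..2m-1 are class 0 / band 0.
    """

    data: np.ndarray
    index_map: list[tuple[int, int, int]]
    labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.data.shape[1] != len(self.index_map):
            raise ValueError("index_map length must equal D")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def D(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def trial_covariance(X: np.ndarray, ridge: float = 1e-8,
                     trace_normalize: bool = False) -> np.ndarray:
    """Spatial covariance (C x C) of one trial, mean-centered per channel.

    Returns ``X_c X_c' / T`` plus a relative ridge ``ridge * (trace/C) * I``
    that keeps the estimate positive definite when a channel is (numerically)
    constant.  ``trace_normalize=True`` divides by the trace first (a common
    practice variant that equalizes trial power); the plain average is the
    default.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError(f"need a [channels, samples>=2] array, got {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("trial contains NaN or Inf")
    Xc = X - X.mean(axis=1, keepdims=True)
    C = (Xc @ Xc.T) / X.shape[1]
    C = 0.5 * (C + C.T)
    tr = np.trace(C)
    if trace_normalize:
        if tr <= 0:
            raise ValueError("cannot trace-normalize a zero-power trial")
        C = C / tr
        tr = 1.0
    scale = tr / X.shape[0] if tr > 0 else 1.0
    return C + ridge * scale * np.eye(X.shape[0])


def class_covariances(
    band_epochs: BandEpochs,
    labels: np.ndarray | None = None,
    ridge: float = 1e-8,
    trace_normalize: bool = False,
    rest_pooling: str = "trials",
) -> dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]:
    """Average (Sigma_k, Sigma_rest) covariance pairs per (class, band).

    Sigma_k is the mean trial covariance over class-k trials.  Sigma_rest
    pools the other classes either over all their trials
    (``rest_pooling="trials"``, the default: equivalently trial-weighted)
    or as the unweighted mean of the other per-class means
    (``rest_pooling="classes"``).  The two coincide for balanced designs.
    """
    if rest_pooling not in ("trials", "classes"):
        raise ValueError(f"rest_pooling must be 'trials' or 'classes', got {rest_pooling!r}")
    labels = band_epochs.labels if labels is None else np.asarray(labels)
    classes = np.unique(labels)
    for cls in classes:
        if (labels == cls).sum() < 2:
            raise ValueError(f"class {cls} has fewer than 2 trials; cannot estimate covariance")
    n, F = band_epochs.n_trials, band_epochs.n_bands
    C = band_epochs.n_channels
    # per-trial covariances once, reused for every one-vs-rest split
    covs = np.empty((n, F, C, C))
    for i in range(n):
        for f in range(F):
            covs[i, f] = trial_covariance(band_epochs.data[i, f], ridge=ridge,
                                          trace_normalize=trace_normalize)
    class_means = {int(k): covs[labels == k].mean(axis=0) for k in classes}
    out: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for k in classes:
        k = int(k)
        if rest_pooling == "trials":
            rest = covs[labels != k].mean(axis=0)
        else:
            rest = np.mean([class_means[j] for j in class_means if j != k], axis=0)
        for f in range(F):
            out[(k, f)] = (class_means[k][f], rest[f])
    return out


def _sign_normalize(W: np.ndarray) -> np.ndarray:
    """Unit-normalize columns; flip signs so the largest entry is positive.

    Unit norm (rather than the solver's Sigma_j-normalization) makes the
    returned filters invariant to a common rescaling of the input data.
    """
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def solve_csp(Si: np.ndarray, Sj: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Solve ``Si w = lambda Sj w`` and select the m extreme eigenpairs per end.

    Returns ``(W, lam)`` with W of shape (C, 2m): columns 0..m-1 are the m
    largest-eigenvalue directions (descending), columns m..2m-1 the m
    smallest (ascending).  Columns are sign-normalized.
    """
    Si = np.asarray(Si, dtype=np.float64)
    Sj = np.asarray(Sj, dtype=np.float64)
    C = Si.shape[0]
    if Si.shape != (C, C) or Sj.shape != (C, C):
        raise ValueError("covariances must be square and same size")
    if 2 * m > C:
        raise ValueError(
            f"requested 2m = {2 * m} CSP components but only C = {C} channels are available"
        )
    try:
        lam, V = linalg.eigh(Si, Sj)  # ascending eigenvalues
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"generalized eigensolver failed: {exc}") from exc
    if np.allclose(lam, lam[0], rtol=1e-10, atol=1e-12):
        warnings.warn(
            "degenerate CSP problem (Si ~ Sj up to scale): all eigenvalues equal; "
            "returning the first 2m eigenvectors in solver order",
            stacklevel=2,
        )
        W = V[:, : 2 * m]
        return _sign_normalize(W), lam[: 2 * m].copy()
    top = lam[::-1][:m]  # m largest, descending
    bot = lam[:m]  # m smallest, ascending
    W = np.concatenate([V[:, ::-1][:, :m], V[:, :m]], axis=1)
    return _sign_normalize(W), np.concatenate([top, bot])


def fit_ovr_csp(
    band_epochs: BandEpochs,
    labels: np.ndarray | None = None,
    m: int = 1,
    ridge: float = 1e-8,
    trace_normalize: bool = False,
    rest_pooling: str = "trials",
) -> SpatialFilterBank:
    """Fit one-vs-rest CSP filters for every (class, band) pair.

    Must be called on training trials only; the caller owns leakage control.
    """
    labels = band_epochs.labels if labels is None else np.asarray(labels)
    C = band_epochs.n_channels
    if 2 * m > C:
        raise ValueError(
            f"requested 2m = {2 * m} CSP components but only C = {C} channels are available"
        )
    pairs = class_covariances(band_epochs, labels, ridge=ridge,
                              trace_normalize=trace_normalize,
                              rest_pooling=rest_pooling)
    classes = sorted({k for (k, _) in pairs})
    F = band_epochs.n_bands
    W: list[list[np.ndarray]] = []
    lams = np.empty((len(classes), F, 2 * m))
    for k in classes:
        row = []
        for f in range(F):
            Sk, Srest = pairs[(k, f)]
            Wkf, lam = solve_csp(Sk, Srest, m)
            row.append(Wkf)
            lams[k, f] = lam
        W.append(row)
    return SpatialFilterBank(
        W=W,
        eigenvalues=lams,
        m=m,
        class_names=list(band_epochs.class_names),
        bands=list(band_epochs.bands),
    )


def fuse_virtual_channels(
    band_epochs: BandEpochs, filters: SpatialFilterBank
) -> VirtualChannelSet:
    """Project every trial through every (class, band) filter and concatenate.

    The result is ``V_n`` of shape [n_trials, D, T] with D = K * F * 2m and
    class-major / band-minor / component-last channel ordering: the first 2m
    virtual channels are class 0 in band 0, the next 2m class 0 in band 1,
    and so on.  Full time series are preserved.
    """
    if filters.n_bands != band_epochs.n_bands:
        raise ValueError(
            f"filter bank has {filters.n_bands} bands but data has {band_epochs.n_bands}"
        )
    if filters.n_channels != band_epochs.n_channels:
        raise ValueError(
            f"filter bank expects {filters.n_channels} channels, data has {band_epochs.n_channels}"
        )
    K, F, m = filters.n_classes, filters.n_bands, filters.m
    n, T = band_epochs.n_trials, band_epochs.n_samples
    D = K * F * 2 * m
    out = np.empty((n, D, T))
    index_map: list[tuple[int, int, int]] = []
    d = 0
    for k in range(K):
        for f in range(F):
            Wkf = filters.W[k][f]  # C x 2m
            # Z_n = W' X_n : [n, C, T] -> [n, 2m, T]
            out[:, d : d + 2 * m] = np.einsum(
                "cm,nct->nmt", Wkf, band_epochs.data[:, f], optimize=True
            )
            index_map.extend((k, f, c) for c in range(2 * m))
            d += 2 * m
    return VirtualChannelSet(
        data=out,
        index_map=index_map,
        labels=band_epochs.labels.copy(),
        fs=band_epochs.fs,
    )


def filters_to_patterns(W: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Map spatial filters to the spatial patterns they extract.

    A filter w is a backward-model weight vector; the corresponding forward
    -model pattern (the field distribution of the extracted source) is
    ``A = Sigma W (W' Sigma W)^{-1}`` with Sigma the data covariance in the
    band the filters were fitted on.  Columns of A match columns of W.
    """
    W = np.atleast_2d(np.asarray(W, dtype=np.float64))
    if W.shape[0] == 1:
        W = W.T
    G = W.T @ Sigma @ W
    return Sigma @ W @ np.linalg.inv(G)


def logvar_features(vc: VirtualChannelSet, eps: float = 1e-12) -> np.ndarray:
    """Log temporal variance per virtual channel: the classic FBCSP feature.

    This is the compression MCFANet deliberately avoids; it is kept for the
    FBCSP/CSP baselines.  Zero-variance channels are floored at log(eps).
    """
    if vc.n_samples < 2:
        raise ValueError("need at least 2 samples to compute a variance")
    var = vc.data.var(axis=2)
    if (var <= 0).any():
        warnings.warn("zero-variance virtual channel; flooring at log(eps)", stacklevel=2)
    return np.log(np.maximum(var, eps))
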