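"""Labeled EEG epochs, fixture I/O, and stratified fold construction.

An :class:`EpochSet` is the universal input of the pipeline: a dense
``[n_trials, n_channels, n_samples]`` array of band-limited EEG voltage
traces, one integer class label per trial, the sampling rate, and display
metadata (channel and class names, subject id).

On disk an epoch set is a pair of files: ``<name>.epochs`` (a NumPy array
container holding the tensor) and ``<name>.json`` (a sidecar with the
sampling rate, labels and names).  The sidecar is plain JSON so metadata
stays diffable and language-neutral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EpochSet", "FoldPlan", "load_epochs", "save_epochs", "stratified_folds"]


class EpochsFormatError(ValueError):
    """Raised when an on-disk fixture is missing pieces or corrupt."""


class EpochsValidationError(ValueError):
    """Raised when epoch data violate an :class:`EpochSet` invariant."""


@dataclass
class EpochSet:
    """Labeled multi-channel EEG trials.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Voltage traces. Each trial is one cue-aligned window X_n in R^{C x T}.
    labels : ndarray of int, shape (n_trials,)
        Class index per trial, in ``0..K-1``.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    class_names : list of str
        Display names, length K ("Left Hand", ...).
    subject_id : str
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1] if self.data.ndim == 3 else 0)]
        if not self.class_names:
            k = int(self.labels.max()) + 1 if self.labels.size else 0
            self.class_names = [f"class{i}" for i in range(k)]
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise EpochsValidationError(f"data must be 3-d [trials, channels, samples], got {self.data.shape}")
        if self.data.shape[2] < 1:
            raise EpochsValidationError("n_samples must be positive")
        if self.labels.shape != (self.data.shape[0],):
            raise EpochsValidationError(
                f"labels length {self.labels.shape} does not match {self.data.shape[0]} trials"
            )
        if self.fs <= 0:
            raise EpochsValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[1]:
            raise EpochsValidationError("channel_names length does not match n_channels")
        k = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= k):
            raise EpochsValidationError(
                f"labels must lie in 0..{k - 1}, got range [{self.labels.min()}, {self.labels.max()}]"
            )
        if not np.isfinite(self.data).all():
            raise EpochsValidationError("data contains NaN or Inf")

    def select(self, idx: np.ndarray) -> "EpochSet":
        """Return a new EpochSet restricted to trials ``idx`` (order kept)."""
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            labels=self.labels[idx],
            fs=self.fs,
            channel_names=list(self.channel_names),
            class_names=list(self.class_names),
            subject_id=self.subject_id,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpochSet):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
            and self.fs == other.fs
            and self.channel_names == other.channel_names
            and self.class_names == other.class_names
            and self.subject_id == other.subject_id
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Persist an EpochSet as ``<path>.epochs`` + ``<path>.json``.

    The representation round-trips bit-exactly through :func:`load_epochs`,
    and repeated saves of the same object are byte-identical.
    """
    epochs.validate()
    if epochs.n_trials == 0:
        raise EpochsValidationError("refusing to persist an EpochSet with zero trials")
    path = Path(path)
    if path.suffix != ".epochs":
        path = path.with_suffix(".epochs")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        np.save(fh, epochs.data)
    sidecar = {
        "fs": epochs.fs,
        "labels": epochs.labels.tolist(),
        "channel_names": epochs.channel_names,
        "class_names": epochs.class_names,
        "subject_id": epochs.subject_id,
        "shape": list(epochs.data.shape),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path


def load_epochs(path: str | Path) -> EpochSet:
    """Load and validate an EpochSet saved by :func:`save_epochs`."""
    path = Path(path)
    if path.suffix != ".epochs":
        path = path.with_suffix(".epochs")
    if not path.exists():
        raise EpochsFormatError(f"missing array container {path}")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise EpochsFormatError(f"missing JSON sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise EpochsFormatError(f"corrupt sidecar {sidecar_path}: {exc}") from exc
    for key in ("fs", "labels", "channel_names", "class_names"):
        if key not in meta:
            raise EpochsFormatError(f"sidecar {sidecar_path} lacks required key '{key}'")
    data = np.load(path)
    if "shape" in meta and list(data.shape) != meta["shape"]:
        raise EpochsFormatError(
            f"array shape {data.shape} disagrees with sidecar shape {meta['shape']}"
        )
    return EpochSet(
        data=data,
        labels=np.asarray(meta["labels"], dtype=np.int64),
        fs=float(meta["fs"]),
        channel_names=list(meta["channel_names"]),
        class_names=list(meta["class_names"]),
        subject_id=str(meta.get("subject_id", "")),
    )


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class FoldPlan:
    """A stratified k-fold partition of trials.

    ``assignments[i]`` is the fold index of trial ``i``.  Folds are disjoint,
    exhaustive, and each contains at least one trial of every class; per-class
    counts differ by at most one across folds.
    """

    k: int
    assignments: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> FoldPlan:
    """Build a class-stratified k-fold plan, deterministic under ``seed``.

    Within each class, trials are shuffled and dealt round-robin to folds,
    so per-class counts across folds differ by at most one.

    Raises
    ------
    ValueError
        If any class has fewer than ``k`` members (an empty-class fold
        would make per-fold metrics undefined).
    """
    labels = np.asarray(labels, dtype=np.int64)
    if k < 2:
        raise ValueError(f"need at least 2 folds, got k={k}")
    rng = np.random.default_rng(seed)
    assignments = np.full(labels.shape[0], -1, dtype=np.int64)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls} has only {idx.size} trials; cannot stratify into {k} folds"
            )
        rng.shuffle(idx)
        assignments[idx] = np.arange(idx.size) % k
    return FoldPlan(k=k, assignments=assignments, seed=seed)
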