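"""Leakage-free cross-validated evaluation and the grid search over m.

The protocol: stratified k-fold (k = 5 by default); within each fold every
data-dependent operation — band-pass filtering statistics, CSP filter
estimation, network training — happens on the training split only, by
fitting a fresh clone of the estimator on the training trials; the fitted
estimator is then applied to both splits.  Per-subject results aggregate
fold predictions by concatenation, then summing confusion matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.metrics import confusion_matrix, f1_score

from .epochs import EpochSet, FoldPlan, stratified_folds

__all__ = ["CVReport", "run_cv", "grid_search_m", "permutation_cv"]


@dataclass
class CVReport:
    """Per-fold and aggregated cross-validation results."""

    k: int
    fold_accuracies: np.ndarray  # [k]
    fold_macro_f1: np.ndarray  # [k]
    predictions: np.ndarray  # [n], aligned with trial order
    labels: np.ndarray  # [n]
    fold_assignments: np.ndarray  # [n]
    train_indices: list  # per fold, the trial indices the estimator saw in fit
    per_class_f1: np.ndarray  # aggregated over concatenated predictions
    confusion: np.ndarray  # [K, K] counts, rows = true class
    config: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.fold_accuracies.std(ddof=1))

    @property
    def aggregate_accuracy(self) -> float:
        """Accuracy over concatenated predictions == trace / total."""
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def confusion_percent(self) -> np.ndarray:
        """Row-normalized confusion (percent of each true class)."""
        rows = self.confusion.sum(axis=1, keepdims=True)
        return 100.0 * self.confusion / np.maximum(rows, 1)

    @property
    def macro_f1(self) -> float:
        return float(self.per_class_f1.mean())

    def summary(self) -> dict:
        return {
            "k": self.k,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "macro_f1": self.macro_f1,
            "fold_accuracies": self.fold_accuracies.tolist(),
            "per_class_f1": self.per_class_f1.tolist(),
            "confusion": self.confusion.tolist(),
            "config": self.config,
        }


def run_cv(epochs: EpochSet, estimator, k: int = 5, seed: int = 0,
           plan: FoldPlan | None = None) -> CVReport:
    """Stratified k-fold cross-validation of a cloneable estimator.

    A fresh clone is fitted per fold on the training trials only; the
    indices it saw are recorded in the report so leakage is auditable.
    """
    labels = epochs.labels
    plan = plan or stratified_folds(labels, k, seed)
    n = epochs.n_trials
    preds = np.full(n, -1, dtype=np.int64)
    accs, f1s, train_idx_per_fold = [], [], []
    for fold in range(plan.k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        est = clone(estimator)
        est.fit(epochs.data[tr], labels[tr])
        p = np.asarray(est.predict(epochs.data[te]))
        preds[te] = p
        accs.append(float((p == labels[te]).mean()))
        f1s.append(float(f1_score(labels[te], p, average="macro", zero_division=0)))
        train_idx_per_fold.append(tr)
    classes = np.unique(labels)
    conf = confusion_matrix(labels, preds, labels=classes)
    per_class = f1_score(labels, preds, average=None, labels=classes, zero_division=0)
    try:
        config = dict(estimator.get_params())
    except Exception:  # estimator without sklearn params
        config = {}
    config.update({"k": plan.k, "seed": plan.seed})
    return CVReport(
        k=plan.k,
        fold_accuracies=np.asarray(accs),
        fold_macro_f1=np.asarray(f1s),
        predictions=preds,
        labels=labels.copy(),
        fold_assignments=plan.assignments.copy(),
        train_indices=train_idx_per_fold,
        per_class_f1=np.asarray(per_class),
        confusion=conf,
        config=config,
    )


def grid_search_m(epochs: EpochSet, estimator, grid=(1, 2, 3, 4, 5),
                  k: int = 5, seed: int = 0) -> tuple[int, dict[int, CVReport]]:
    """Cross-validated grid search over the CSP filter-pair count m.

    Values with 2m > n_channels are skipped with a warning.  Returns the m
    with the highest mean accuracy (ties broken toward the smallest m) and
    the per-m reports.
    """
    C = epochs.n_channels
    reports: dict[int, CVReport] = {}
    for m in sorted(grid):
        if 2 * m > C:
            warnings.warn(
                f"skipping m={m}: 2m = {2 * m} exceeds the {C} channels",
                stacklevel=2,
            )
            continue
        reports[m] = run_cv(epochs, clone(estimator).set_params(m=m), k=k, seed=seed)
    if not reports:
        raise ValueError("no feasible m in the grid")
    best = max(sorted(reports), key=lambda m: reports[m].mean_accuracy)
    # max() keeps the first (smallest) m on exact ties because of the sort
    return best, reports


def permutation_cv(epochs: EpochSet, estimator, k: int = 5, seed: int = 0,
                   perm_seed: int = 1) -> CVReport:
    """Run the CV protocol with labels randomly permuted (chance control)."""
    rng = np.random.default_rng(perm_seed)
    shuffled = EpochSet(
        data=epochs.data,
        labels=rng.permutation(epochs.labels),
        fs=epochs.fs,
        channel_names=list(epochs.channel_names),
        class_names=list(epochs.class_names),
        subject_id=epochs.subject_id,
    )
    return run_cv(shuffled, estimator, k=k, seed=seed)
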