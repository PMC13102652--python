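"""Thin pipeline wrappers over the baseline estimators.

These mirror the comparison points that share the core machinery:
FBEEGNet (single-filter-set ablation), FBCSP (log-variance + LDA),
broadband CSP, and the plain backbone on raw channels.  Each function
fits on the training epochs only and returns predictions for the test set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet
from .estimators import (
    BackboneRawClassifier,
    CSPClassifier,
    FBCSPClassifier,
    FBEEGNetClassifier,
)

__all__ = ["BaselineSpec", "make_baseline", "fbeegnet_pipeline",
           "fbcsp_pipeline", "csp_pipeline", "backbone_raw_pipeline"]

_NAMES = ("fbeegnet", "fbcsp", "csp", "backbone_raw")


@dataclass(frozen=True)
class BaselineSpec:
    """Which baseline to run and with what capacity."""

    name: str
    m: int = 1
    reference_class: int = 0
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in _NAMES:
            raise ValueError(f"baseline name must be one of {_NAMES}")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.reference_class < 0:
            raise ValueError("reference_class must be a class index")


def make_baseline(spec: BaselineSpec, fs: float):
    if spec.name == "fbeegnet":
        return FBEEGNetClassifier(m=spec.m, reference_class=spec.reference_class,
                                  fs=fs, epochs=spec.epochs, seed=spec.seed)
    if spec.name == "fbcsp":
        return FBCSPClassifier(m=spec.m, fs=fs)
    if spec.name == "csp":
        return CSPClassifier(m=spec.m, fs=fs)
    return BackboneRawClassifier(fs=fs, epochs=spec.epochs, seed=spec.seed)


def _run(train: EpochSet, test: EpochSet, spec: BaselineSpec, expected: str
         ) -> np.ndarray:
    if spec.name != expected:
        raise ValueError(f"spec names {spec.name!r}, not {expected!r}")
    est = make_baseline(spec, fs=train.fs)
    est.fit(train.data, train.labels)
    return np.asarray(est.predict(test.data))


def fbeegnet_pipeline(train: EpochSet, test: EpochSet, spec: BaselineSpec
                      ) -> np.ndarray:
    """Single-filter-set filter-bank pipeline into the backbone (D' = F*2m)."""
    return _run(train, test, spec, "fbeegnet")


def fbcsp_pipeline(train: EpochSet, test: EpochSet, spec: BaselineSpec
                   ) -> np.ndarray:
    """One-vs-rest CSP per band -> log-variance -> shrinkage LDA."""
    return _run(train, test, spec, "fbcsp")


def csp_pipeline(train: EpochSet, test: EpochSet, spec: BaselineSpec
                 ) -> np.ndarray:
    """Broadband 8-32 Hz CSP -> log-variance -> shrinkage LDA."""
    return _run(train, test, spec, "csp")


def backbone_raw_pipeline(train: EpochSet, test: EpochSet, spec: BaselineSpec
                          ) -> np.ndarray:
    """The CNN backbone on raw channels, no spatial filtering."""
    return _run(train, test, spec, "backbone_raw")
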