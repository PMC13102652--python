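"""Checkpointing of fitted CNN estimators.

A checkpoint is a single ``.npz`` parameter archive whose ``meta`` entry is
a JSON architecture descriptor (estimator class, constructor parameters,
input geometry, class labels, filter-bank metadata).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .csp import SpatialFilterBank
from .estimators import FBEEGNetClassifier, MCFANetClassifier
from .filterbank import BandSpec
from .nn import NetConfig, build_mcfanet

__all__ = ["save_model", "load_model"]

_KINDS = {"MCFANetClassifier": MCFANetClassifier,
          "FBEEGNetClassifier": FBEEGNetClassifier}


def save_model(est, path: str | Path) -> Path:
    """Persist a fitted MCFANet/FBEEGNet estimator to ``<path>.npz``."""
    kind = type(est).__name__
    if kind not in _KINDS:
        raise TypeError(f"cannot checkpoint estimator of type {kind}")
    if not hasattr(est, "net_"):
        raise ValueError("estimator is not fitted")
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    bank = est.filters_
    arrays = {f"W_{k}_{f}": bank.W[k][f]
              for k in range(bank.n_classes) for f in range(bank.n_bands)}
    arrays["eigenvalues"] = bank.eigenvalues
    arrays["classes"] = est.classes_
    arrays.update(est.net_.state_arrays())
    meta = {
        "kind": kind,
        "params": est.get_params(),
        "net": asdict(est.net_.cfg),
        "D": est.net_.D,
        "T": est.net_.T,
        "m": bank.m,
        "bank_classes": bank.n_classes,
        "bands": [b.as_tuple() for b in bank.bands],
        "class_names": bank.class_names,
        "index_map": est.index_map_,
    }
    with open(path, "wb") as fh:
        np.savez(fh, meta=json.dumps(meta), **arrays)
    return path


def load_model(path: str | Path):
    """Rebuild a fitted estimator from :func:`save_model` output."""
    with np.load(Path(path), allow_pickle=False) as archive:
        state = {k: archive[k] for k in archive.files}
    meta = json.loads(str(state.pop("meta")))
    est = _KINDS[meta["kind"]](**meta["params"])
    est.classes_ = state.pop("classes")
    K, F = meta["bank_classes"], len(meta["bands"])
    est.filters_ = SpatialFilterBank(
        W=[[state.pop(f"W_{k}_{f}") for f in range(F)] for k in range(K)],
        eigenvalues=state.pop("eigenvalues"),
        m=meta["m"],
        class_names=list(meta["class_names"]),
        bands=[BandSpec(*b) for b in meta["bands"]],
    )
    est.index_map_ = [tuple(e) for e in meta["index_map"]]
    est.net_ = build_mcfanet(meta["D"], meta["T"], NetConfig(**meta["net"]))
    est.net_.load_state_arrays(state)
    return est
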