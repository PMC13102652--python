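"""Shared fixtures: all data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from mcfanet import EpochSet, SynthConfig, generate


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_epochs(rng) -> EpochSet:
    """8 random trials, 4 channels, 500 samples at 250 Hz, 4 classes."""
    return EpochSet(
        data=rng.standard_normal((8, 4, 500)),
        labels=np.array([0, 1, 2, 3, 0, 1, 2, 3]),
        fs=250.0,
        class_names=["Left Hand", "Right Hand", "Foot", "Tongue"],
        subject_id="S00",
    )


@pytest.fixture(scope="session")
def tiny_mode_a() -> EpochSet:
    """Small high-SNR mode-A dataset for protocol-level tests (fast)."""
    cfg = SynthConfig(n_channels=6, n_samples=250, trials_per_class=12,
                      class_bands=((8, 12), (12, 16), (20, 24), (28, 32)),
                      snr_db=12.0, mode="A", seed=7)
    return generate(cfg)
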