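"""Optional reader hook for standard EEG recordings (EDF/GDF).

Maps a raw recording plus event annotations to an :class:`EpochSet` with a
post-cue crop, using MNE when it is installed (``pip install mcfanet[eeg]``).
This adapter is deliberately minimal: montage handling, artifact rejection
and resampling stay out of scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .epochs import EpochSet

__all__ = ["read_raw_epochs"]


def read_raw_epochs(path: str | Path, event_ids: dict[str, int],
                    tmin: float = 0.0, tmax: float = 4.0,
                    picks: list[str] | None = None,
                    subject_id: str = "") -> EpochSet:
    """Epoch an EDF/GDF recording around cue annotations.

    Parameters
    ----------
    event_ids : mapping of annotation description -> class index (0..K-1),
        e.g. ``{"769": 0, "770": 1, "771": 2, "772": 3}`` for the standard
        four-class cue codes.
    tmin, tmax : crop window in seconds relative to the cue (default 0-4 s).
    picks : channel names to keep (default: all EEG channels).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF/GDF requires the optional 'mne' dependency"
        ) from exc
    path = Path(path)
    reader = mne.io.read_raw_gdf if path.suffix.lower() == ".gdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    if picks:
        raw.pick(picks)
    else:
        raw.pick("eeg")
    events, ann_map = mne.events_from_annotations(raw, verbose="error")
    selected = {desc: code for desc, code in ann_map.items() if desc in event_ids}
    if not selected:
        raise ValueError(
            f"none of {sorted(event_ids)} found in annotations {sorted(ann_map)}"
        )
    epochs = mne.Epochs(
        raw, events,
        event_id=selected,
        tmin=tmin, tmax=tmax, baseline=None, preload=True, verbose="error",
    )
    data = epochs.get_data(copy=True)[:, :, :-1]  # drop the inclusive endpoint
    code_to_class = {selected[desc]: event_ids[desc] for desc in selected}
    labels = np.array([code_to_class[c] for c in epochs.events[:, 2]])
    k = int(labels.max()) + 1
    return EpochSet(
        data=data,
        labels=labels,
        fs=float(raw.info["sfreq"]),
        channel_names=list(epochs.ch_names),
        class_names=[f"class{i}" for i in range(k)],
        subject_id=subject_id or path.stem,
    )
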