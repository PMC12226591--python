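"""Ingestion of recorded EEG into the trial container.

Real recordings (BrainVision ``.vhdr`` or EDF+) are read through MNE; the
epoching into peri-stimulation trial records then follows the same window
arithmetic as the synthetic pipeline.  MNE is an optional dependency — it is
imported only when these functions are called.
"""

from __future__ import annotations

import numpy as np

from .preprocess import extract_epochs
from .synthetic import TrialRecord

__all__ = ["read_raw", "trials_from_raw"]


def read_raw(path: str, **kwargs):
    """Open a BrainVision / EDF+ / FIF recording via :func:`mne.io.read_raw`."""
    import mne

    return mne.io.read_raw(path, preload=True, verbose="error", **kwargs)


def trials_from_raw(
    raw,
    retention_onsets_s: np.ndarray,
    conditions: np.ndarray,
    channels: tuple[str, ...],
    participant: int = 0,
    session: int = 0,
    windows: tuple[tuple[float, float], ...] = ((0.0, 0.5), (8.5, 9.0)),
    to_microvolts: float = 1e6,
) -> list[TrialRecord]:
    """Cut peri-stimulation trial records out of an MNE ``Raw`` object.

    Parameters
    ----------
    retention_onsets_s
        Retention-period onset of each trial, seconds from recording start.
    conditions
        Per-trial phase-lag condition (45 or 180).
    channels
        Analysis channels, in the canonical order to store.
    to_microvolts
        Scale from the Raw units (MNE uses volts) to microvolts.
    """
    fs = float(raw.info["sfreq"])
    picks = [raw.ch_names.index(c) for c in channels]
    data = raw.get_data(picks=picks) * to_microvolts  # (C, n_samples)
    trials = []
    for onset_s, cond in zip(retention_onsets_s, conditions):
        onset = int(round(onset_s * fs))
        pre, post = extract_epochs(data, onset, fs, windows)
        trials.append(
            TrialRecord(
                participant=participant,
                session=session,
                condition=int(cond),
                pre=pre,
                post=post,
            )
        )
    return trials
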