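"""Real-data mode: epoch continuous EEG recordings into an EpochMatrix.

The pipeline itself is container-agnostic; this module turns a
continuous multichannel recording (an EDF/BDF file, or any in-memory
`mne.io.Raw`) plus a tidy event table into the same `EpochMatrix` the
synthetic generator produces. Event tables are TSV with one row per
stimulus: onset_s, block, load, tone_condition, role, frequency,
is_target, is_warmup.

mne is imported lazily: synthetic-only use needs no EEG I/O stack.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_eeg import EpochMatrix, SimulationError

EVENT_COLUMNS = ("onset_s", "block", "load", "tone_condition", "role",
                 "frequency", "is_target", "is_warmup")


def read_events_tsv(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise SimulationError(f"event table missing columns: {sorted(missing)}")
    return events


def epoch_raw(
    raw,
    events: pd.DataFrame,
    channels: tuple[str, ...] = ("Fz", "Cz", "Pz", "P9", "P10"),
    tmin_s: float = -0.1,
    tmax_s: float = 0.5,
    reference: str = "nose",
) -> EpochMatrix:
    """Cut stimulus-locked epochs from an mne Raw into an EpochMatrix (uV)."""
    fs = float(raw.info["sfreq"])
    picks = [raw.ch_names.index(c) for c in channels if c in raw.ch_names]
    if len(picks) != len(channels):
        missing = set(channels) - set(raw.ch_names)
        raise SimulationError(f"recording lacks channels: {sorted(missing)}")
    data = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
    k0 = int(np.ceil(tmin_s * fs - 1e-9))
    k1 = int(np.floor(tmax_s * fs + 1e-9))
    times_ms = np.arange(k0, k1 + 1) * 1000.0 / fs
    n_t = k1 - k0 + 1

    onsets = np.round(events["onset_s"].to_numpy() * fs).astype(int)
    starts, stops = onsets + k0, onsets + k1 + 1
    ok = (starts >= 0) & (stops <= data.shape[1])
    if not ok.all():
        raise SimulationError(
            f"{int((~ok).sum())} events fall outside the recording")
    epochs = np.stack([data[:, a:b] for a, b in zip(starts, stops)])
    assert epochs.shape == (len(events), len(channels), n_t)
    info = events[list(EVENT_COLUMNS[1:])].reset_index(drop=True)
    return EpochMatrix(tuple(channels), fs, times_ms, epochs, info, reference)


def read_continuous_edf(path, events_tsv, **kwargs) -> EpochMatrix:
    """Load an EDF/BDF recording and its event TSV into an EpochMatrix."""
    import mne

    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose=False)
    return epoch_raw(raw, read_events_tsv(events_tsv), **kwargs)
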