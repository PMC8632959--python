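"""Reading and writing EEG recordings.

Wide CSV (`time_s` plus one column per channel) is the round-trip format.
EDF reading is delegated to MNE; EDF writing requires MNE's optional
export backend and raises a clear error when it is unavailable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import EEGRecording

__all__ = ["read_csv", "write_csv", "read_edf", "write_edf"]


def write_csv(rec: EEGRecording, path) -> None:
    """Write a recording as wide CSV: time_s, then one column per channel."""
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for i, label in enumerate(rec.channel_labels):
        df[label] = rec.data[i]
    df.to_csv(path, index=False)


def read_csv(path) -> EEGRecording:
    """Read a wide-CSV recording; fs is inferred from the time_s column."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("wide EEG CSV requires a time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("need at least two samples to infer fs")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("time_s must be uniformly sampled")
    fs = 1.0 / dt[0]
    channels = [c for c in df.columns if c != "time_s"]
    data = df[channels].to_numpy(dtype=float).T
    return EEGRecording(data, fs, channels)


def read_edf(path) -> EEGRecording:
    """Read an EDF file via MNE (values converted volts -> microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecording(raw.get_data() * 1e6, raw.info["sfreq"], raw.ch_names)


def write_edf(rec: EEGRecording, path) -> None:
    """Write an EDF file via MNE's export (needs the edfio backend)."""
    import mne

    info = mne.create_info(rec.channel_labels, rec.fs, ch_types="eeg")
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    try:
        raw.export(str(path), fmt="edf", overwrite=True, verbose="error")
    except (ImportError, RuntimeError) as exc:  # pragma: no cover
        raise RuntimeError(
            "EDF export requires MNE's optional 'edfio' backend; "
            "use write_csv for a dependency-free round trip"
        ) from exc
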