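"""Reading and writing the pipeline's file formats.

Signals come in as EDF (one named PPG/plethysmogram channel, read through
MNE) or as a one-column CSV of samples with the sampling rate supplied
separately; hypnograms are two-column CSV (epoch_index, stage).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def read_ppg_csv(path: str | Path) -> np.ndarray:
    """One-column CSV of PPG samples (header optional)."""
    df = pd.read_csv(path)
    if df.shape[1] != 1:
        raise ValueError(f"expected a one-column samples CSV, got {df.shape[1]} columns")
    return df.iloc[:, 0].to_numpy(dtype=float)


def read_hypnogram_csv(path: str | Path) -> list[str]:
    """Two-column CSV (epoch_index, stage), returned in epoch order."""
    df = pd.read_csv(path)
    if "stage" not in df.columns:
        raise ValueError("hypnogram CSV must have a 'stage' column")
    if "epoch_index" in df.columns:
        df = df.sort_values("epoch_index")
    return [str(s) for s in df["stage"]]


def read_ppg_edf(path: str | Path, channel: str = "PLETH") -> tuple[np.ndarray, float]:
    """Extract one PPG channel from an EDF recording.

    Returns ``(samples, sampling_rate)``.  Requires the optional ``mne``
    dependency; channel matching is case-insensitive.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF input requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    match = [ch for ch in raw.ch_names if ch.strip().upper() == channel.strip().upper()]
    if not match:
        raise ValueError(f"channel {channel!r} not found; available: {raw.ch_names}")
    raw = raw.pick(match).load_data(verbose="error")
    return raw.get_data()[0], float(raw.info["sfreq"])


def write_predictions_csv(path: str | Path, epoch_index, true, predicted) -> None:
    pd.DataFrame(
        {"epoch_index": epoch_index, "true": true, "predicted": predicted}
    ).to_csv(path, index=False)


def read_predictions_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("true", "predicted"):
        if col not in df.columns:
            raise ValueError(f"predictions CSV must have a '{col}' column")
    return df
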