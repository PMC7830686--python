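"""Wavelet denoising and 30-s epoching of raw PPG.

Denoising uses the biorthogonal-3.5 wavelet: the deepest approximation band
(which holds baseline drift) is zeroed, and detail bands above ~20 Hz
(power-line interference and broadband noise) are soft-thresholded with the
universal threshold.  The pulse band in between is left untouched.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pywt

from ppgsleep.labeling import normalize_stage
from ppgsleep.synthetic import NightRecording

logger = logging.getLogger(__name__)

WAVELET = "bior3.5"
#: Decomposition boundary handling.  Periodization makes the transform a
#: bijection on the coefficient space, so re-denoising an already denoised
#: signal is an exact no-op.
WAVELET_MODE = "periodization"


@dataclass
class EpochSignal:
    """One 30-s window of PPG samples u_1 … u_N with its stage label."""

    samples: np.ndarray
    sampling_rate: float
    epoch_index: int
    stage: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        n_expected = round(30 * self.sampling_rate)
        if len(self.samples) != n_expected:
            raise ValueError(
                f"epoch must hold 30 s of samples ({n_expected}), got {len(self.samples)}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("epoch samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)


def _decomposition_level(sampling_rate: float, max_passband_hz: float = 0.35) -> int:
    # deepest approximation band [0, fs / 2^(L+1)] must sit below the
    # slowest physiologic pulse content
    return max(1, math.ceil(math.log2(sampling_rate / max_passband_hz)) - 1)


def denoise(
    samples: np.ndarray,
    sampling_rate: float,
    *,
    max_passband_hz: float = 0.35,
    threshold_above_hz: float = 20.0,
) -> np.ndarray:
    """Remove baseline drift and high-frequency interference from raw PPG.

    Parameters
    ----------
    samples : array-like
        Raw signal; must be finite and long enough for the decomposition
        depth implied by the sampling rate.
    sampling_rate : float
        Sampling rate in Hz.
    max_passband_hz : float
        The deepest approximation band is chosen to cover less than this
        frequency; everything below it is treated as drift and removed.
    threshold_above_hz : float
        Detail bands whose upper edge exceeds this frequency are
        soft-thresholded (universal threshold, noise scale from the median
        absolute deviation of the finest detail level).

    Returns
    -------
    ndarray of the same length as the input.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    level = _decomposition_level(sampling_rate, max_passband_hz)
    min_len = 2**level
    if len(x) < min_len:
        raise ValueError(
            f"need at least {min_len} samples (2^{level}) for a depth-{level} "
            f"decomposition at {sampling_rate} Hz; got {len(x)}"
        )
    coeffs = pywt.wavedec(x, WAVELET, mode=WAVELET_MODE, level=level)
    coeffs[0] = np.zeros_like(coeffs[0])  # approximation band = baseline drift

    finest = coeffs[-1]
    sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
    threshold = sigma * math.sqrt(2.0 * math.log(len(x)))
    for d in range(1, level + 1):  # detail level d spans [fs/2^(d+1), fs/2^d]
        if sampling_rate / 2**d > threshold_above_hz and threshold > 0:
            coeffs[-d] = pywt.threshold(coeffs[-d], threshold, mode="soft")

    return pywt.waverec(coeffs, WAVELET, mode=WAVELET_MODE)[: len(x)]


def epochize(
    recording: NightRecording | np.ndarray,
    hypnogram: list[str] | None = None,
    sampling_rate: float | None = None,
    epoch_length_s: float = 30.0,
) -> list[EpochSignal]:
    """Slice a recording into annotated 30-s epochs, dropping unscored ones.

    Accepts either a :class:`NightRecording` or a raw sample array plus
    ``hypnogram`` and ``sampling_rate``.  Any hypnogram label outside the
    recognized six-stage vocabulary (e.g. MT, movement time) is treated as
    unscored and the epoch is excluded; ordering and epoch indices of the
    remaining epochs are preserved.
    """
    if isinstance(recording, NightRecording):
        samples = recording.samples
        hypnogram = recording.hypnogram
        sampling_rate = recording.sampling_rate
        epoch_length_s = recording.epoch_length_s
    else:
        samples = np.asarray(recording, dtype=float)
        if hypnogram is None or sampling_rate is None:
            raise ValueError("raw-sample input requires hypnogram and sampling_rate")

    n_per_epoch_f = epoch_length_s * sampling_rate
    n_per_epoch = round(n_per_epoch_f)
    if abs(n_per_epoch_f - n_per_epoch) > 1e-9:
        raise ValueError(
            f"epoch length x sampling rate must be an integer sample count, "
            f"got {n_per_epoch_f}"
        )
    if len(hypnogram) * n_per_epoch > len(samples):
        raise ValueError(
            f"hypnogram ({len(hypnogram)} epochs) longer than signal "
            f"({len(samples) // n_per_epoch} whole epochs)"
        )

    epochs: list[EpochSignal] = []
    n_dropped = 0
    for i, raw_label in enumerate(hypnogram):
        stage = normalize_stage(raw_label)
        if stage is None:
            n_dropped += 1
            continue
        seg = samples[i * n_per_epoch : (i + 1) * n_per_epoch]
        epochs.append(
            EpochSignal(samples=seg, sampling_rate=sampling_rate, epoch_index=i, stage=stage)
        )
    if n_dropped:
        logger.info("dropped %d unscored epoch(s)", n_dropped)
    return epochs
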