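"""Pulse-peak detection and heart-rate-variability spectral band powers.

From a denoised 30-s PPG epoch, systolic peaks are located with an
adaptive-threshold detector, the RR tachogram is built from successive peak
times, resampled to an even 4-Hz grid by cubic interpolation, and its Welch
power spectral density is integrated over four bands:

* TLF (true low frequency) 0.04–0.1 Hz
* MF  (medium frequency)   0.1–0.15 Hz
* LF  (low frequency)      0.04–0.15 Hz = TLF ∪ MF
* HF  (high frequency)     0.15–0.4 Hz

Powers are in ms².  Because the LF band is exactly the union of TLF and MF
and band powers are accumulated over the same half-open frequency bins,
LF = TLF + MF holds by construction on every epoch.

A 30-s window cannot cleanly resolve 0.04 Hz; the bands are kept as defined
and the resolution caveat is documented rather than lengthening the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, welch

from ppgsleep.preprocess import EpochSignal

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDefinition:
    """HRV frequency bands (Hz).  LF must equal the union of TLF and MF."""

    tlf: tuple[float, float] = (0.04, 0.1)
    mf: tuple[float, float] = (0.1, 0.15)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        if not (self.lf[0] == self.tlf[0] and self.tlf[1] == self.mf[0] and self.mf[1] == self.lf[1]):
            raise ValueError("LF band must be exactly TLF ∪ MF (shared edges)")


@dataclass
class HrvFeatures:
    lf_power: float
    tlf_power: float
    hf_power: float
    mf_power: float
    flagged: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "lf_power": self.lf_power,
            "tlf_power": self.tlf_power,
            "hf_power": self.hf_power,
            "mf_power": self.mf_power,
        }


def detect_peaks(
    epoch: EpochSignal | np.ndarray,
    sampling_rate: float | None = None,
    *,
    threshold_sd: float = 1.0,
    window_s: float = 2.0,
    refractory_s: float = 0.3,
) -> np.ndarray:
    """Locate systolic pulse peaks; returns beat times in seconds.

    Candidate local maxima (minimum spacing ``refractory_s``, i.e. a 200-bpm
    ceiling) are kept when they exceed a rolling mean + ``threshold_sd`` x
    rolling SD over a ``window_s`` window, then refined to sub-sample
    precision by parabolic interpolation through the three samples around
    each peak (beat-interval spectra are sensitive to timing jitter at the
    sample-period scale).  Peak times are invariant to positive rescaling
    of the signal.
    """
    if isinstance(epoch, EpochSignal):
        x, fs = epoch.samples, epoch.sampling_rate
    else:
        x = np.asarray(epoch, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for raw-array input")
        fs = sampling_rate
    win = max(1, int(window_s * fs))
    mean = uniform_filter1d(x, win)
    sq = uniform_filter1d(x * x, win)
    sd = np.sqrt(np.maximum(sq - mean * mean, 0.0))
    threshold = mean + threshold_sd * sd
    idx, _ = find_peaks(x, distance=max(1, int(refractory_s * fs)))
    idx = idx[x[idx] > threshold[idx]]

    times = idx.astype(float)
    interior = (idx > 0) & (idx < len(x) - 1)
    i = idx[interior]
    curvature = x[i - 1] - 2 * x[i] + x[i + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(curvature < 0, 0.5 * (x[i - 1] - x[i + 1]) / curvature, 0.0)
    times[interior] = i + np.clip(delta, -0.5, 0.5)
    return times / fs


def band_powers(
    beat_times: np.ndarray,
    bands: BandDefinition | None = None,
    *,
    resample_hz: float = 4.0,
    rr_bounds_s: tuple[float, float] = (0.3, 2.0),
) -> HrvFeatures:
    """Integrate the RR-tachogram PSD over the four HRV bands (ms²).

    The RR series is the successive difference of beat times; intervals
    outside ``rr_bounds_s`` (non-physiologic) are dropped before cubic
    interpolation onto an even ``resample_hz`` grid.  The PSD is a
    single-segment Hann-windowed Welch estimate over the whole epoch.

    Fewer than 4 usable beats flags the epoch and returns zero powers.
    """
    if bands is None:
        bands = BandDefinition()
    beat_times = np.asarray(beat_times, dtype=float)
    rr = np.diff(beat_times)
    t_rr = beat_times[1:]
    ok = (rr >= rr_bounds_s[0]) & (rr <= rr_bounds_s[1])
    rr, t_rr = rr[ok], t_rr[ok]
    if len(rr) < 4:
        logger.debug("fewer than 4 usable beats: HRV band powers set to 0")
        return HrvFeatures(0.0, 0.0, 0.0, 0.0, flagged=True)

    rr_ms = rr * 1000.0
    grid = np.arange(t_rr[0], t_rr[-1], 1.0 / resample_hz)
    if len(grid) < 8:
        logger.debug("tachogram span too short for spectral estimation: powers set to 0")
        return HrvFeatures(0.0, 0.0, 0.0, 0.0, flagged=True)
    tach = interp1d(t_rr, rr_ms, kind="cubic")(grid)
    tach = tach - tach.mean()

    freqs, psd = welch(tach, fs=resample_hz, window="hann", nperseg=len(tach), detrend="constant")
    df = freqs[1] - freqs[0]

    def bp(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs < hi)
        return float(psd[mask].sum() * df)

    tlf = bp(*bands.tlf)
    mf = bp(*bands.mf)
    hf = bp(*bands.hf)
    # accumulate LF as TLF + MF over the identical half-open bins so the
    # band-additivity invariant holds exactly
    lf = tlf + mf
    return HrvFeatures(lf_power=lf, tlf_power=tlf, hf_power=hf, mf_power=mf)


def hrv_features(epoch: EpochSignal, bands: BandDefinition | None = None) -> HrvFeatures:
    """Detect peaks in one epoch and compute the four band powers."""
    beats = detect_peaks(epoch)
    if len(beats) < 4:
        logger.debug("epoch %s: %d beat(s) found, HRV flagged", epoch.epoch_index, len(beats))
        return HrvFeatures(0.0, 0.0, 0.0, 0.0, flagged=True)
    return band_powers(beats, bands)
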