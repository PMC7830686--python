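"""Synthetic overnight PPG recordings with stage-dependent cardiac dynamics.

The generator produces a full-night photoplethysmogram as a train of
per-beat pulse templates (systolic peak plus dicrotic bump), where the
inter-beat intervals are drawn from a stage-dependent heart-rate
distribution, and the stage sequence itself is a first-order Markov chain
over the six R&K stages.  Baseline wander, power-line interference and
broadband noise are added on top, so the downstream denoising, peak
detection and feature extraction stages all face the artefacts they are
designed to remove.

The recording carries its own ground-truth beat times, which lets tests
validate the pulse-peak detector and the HRV features against the
simulator's actual draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: The six Rechtschaffen & Kales stage labels, in canonical order.
STAGES: tuple[str, ...] = ("W", "S1", "S2", "S3", "S4", "REM")

EPOCH_LENGTH_S = 30.0

# Row-stochastic transition matrix over (W, S1, S2, S3, S4, REM), one step
# per 30-s epoch.  Strong self-persistence gives realistic bout lengths
# (minutes, not epochs); W/REM occupancy sits near 15% each.
DEFAULT_TRANSITION_MATRIX = np.array(
    [
        [0.880, 0.080, 0.020, 0.000, 0.000, 0.020],
        [0.060, 0.720, 0.180, 0.000, 0.000, 0.040],
        [0.020, 0.030, 0.860, 0.050, 0.000, 0.040],
        [0.010, 0.000, 0.060, 0.850, 0.060, 0.020],
        [0.005, 0.000, 0.010, 0.065, 0.900, 0.020],
        [0.030, 0.020, 0.040, 0.000, 0.000, 0.910],
    ]
)

# Mean heart rate per stage (bpm): wake highest, deep sleep lowest, REM
# close to wake.  Beat-to-beat HR spread is roughly doubled in REM, which
# is the variability signature the classifier has to pick up.
DEFAULT_MEAN_HR_BPM = {"W": 74.0, "S1": 70.0, "S2": 66.0, "S3": 62.0, "S4": 60.0, "REM": 72.0}
DEFAULT_HR_SD_BPM = {"W": 2.0, "S1": 1.8, "S2": 1.5, "S3": 1.2, "S4": 1.0, "REM": 4.0}


class SimulationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic night.

    Heart rates are in beats/min and must lie in (30, 200); the baseline
    wander frequency must stay below 0.5 Hz so it remains a *baseline*
    phenomenon, separable from the pulse band.
    """

    sampling_rate: float = 128.0
    epochs_per_night: int = 960
    stage_transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITION_MATRIX.copy()
    )
    mean_hr_bpm_per_stage: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MEAN_HR_BPM))
    hr_sd_bpm_per_stage: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HR_SD_BPM))
    baseline_wander_amp: float = 0.2
    baseline_wander_freq: float = 0.1
    powerline_freq: float = 50.0
    powerline_amp: float = 0.02
    noise_sd: float = 0.05
    initial_stage: str = "W"
    seed: int = 0

    def __post_init__(self) -> None:
        self.stage_transition_matrix = np.asarray(self.stage_transition_matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise SimulationError("sampling_rate must be positive")
        if self.epochs_per_night < 1:
            raise SimulationError("epochs_per_night must be at least 1")
        P = self.stage_transition_matrix
        if P.shape != (6, 6):
            raise SimulationError(f"stage_transition_matrix must be 6x6, got {P.shape}")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
            raise SimulationError("stage_transition_matrix must be row-stochastic (rows sum to 1)")
        for stage in STAGES:
            hr = self.mean_hr_bpm_per_stage.get(stage)
            if hr is None or not 30.0 < hr < 200.0:
                raise SimulationError(f"mean HR for stage {stage} must lie in (30, 200) bpm")
            sd = self.hr_sd_bpm_per_stage.get(stage)
            if sd is None or sd < 0:
                raise SimulationError(f"HR SD for stage {stage} must be non-negative")
        if not 0 <= self.baseline_wander_freq < 0.5:
            raise SimulationError("baseline_wander_freq must be < 0.5 Hz")
        if self.initial_stage not in STAGES:
            raise SimulationError(f"initial_stage must be one of {STAGES}")

    def to_dict(self) -> dict:
        d = {
            "sampling_rate": self.sampling_rate,
            "epochs_per_night": self.epochs_per_night,
            "stage_transition_matrix": self.stage_transition_matrix.tolist(),
            "mean_hr_bpm_per_stage": dict(self.mean_hr_bpm_per_stage),
            "hr_sd_bpm_per_stage": dict(self.hr_sd_bpm_per_stage),
            "baseline_wander_amp": self.baseline_wander_amp,
            "baseline_wander_freq": self.baseline_wander_freq,
            "powerline_freq": self.powerline_freq,
            "powerline_amp": self.powerline_amp,
            "noise_sd": self.noise_sd,
            "initial_stage": self.initial_stage,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "stage_transition_matrix" in d:
            d["stage_transition_matrix"] = np.asarray(d["stage_transition_matrix"], dtype=float)
        return cls(**d)


@dataclass
class NightRecording:
    """A full-night PPG signal with its aligned per-epoch hypnogram.

    ``beat_times`` (systolic-peak times, seconds from the start of the
    recording) are present only on simulated recordings; real recordings
    carry ``None``.
    """

    samples: np.ndarray
    sampling_rate: float
    hypnogram: list[str]
    epoch_length_s: float = EPOCH_LENGTH_S
    beat_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        expected = round(len(self.hypnogram) * self.epoch_length_s * self.sampling_rate)
        if len(self.samples) != expected:
            raise ValueError(
                f"sample count {len(self.samples)} does not equal "
                f"epochs x epoch_length x sampling_rate = {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return len(self.hypnogram)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate


def simulate_hypnogram(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[str]:
    """Realize the Markov stage chain: one 6-class label per 30-s epoch."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    P = config.stage_transition_matrix
    state = STAGES.index(config.initial_stage)
    hyp = [STAGES[state]]
    for _ in range(config.epochs_per_night - 1):
        state = rng.choice(6, p=P[state])
        hyp.append(STAGES[state])
    return hyp


def _pulse_template(t: np.ndarray, onset: float, rr: float) -> np.ndarray:
    """Two-Gaussian beat shape: systolic peak at 30% of the beat interval,
    dicrotic bump at 65%, amplitude ratio 1 : 0.35."""
    sys_t = onset + 0.30 * rr
    dic_t = onset + 0.65 * rr
    sys_w = 0.08 * rr
    dic_w = 0.12 * rr
    return np.exp(-0.5 * ((t - sys_t) / sys_w) ** 2) + 0.35 * np.exp(
        -0.5 * ((t - dic_t) / dic_w) ** 2
    )


def simulate_night(config: SimulationConfig) -> NightRecording:
    """Generate one synthetic night: PPG samples plus hypnogram.

    Deterministic for a fixed ``config.seed`` (a single seeded generator
    drives the stage chain, the beat draws, and the noise; no global RNG
    state is touched).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    hyp = simulate_hypnogram(config, rng)
    n_epochs = config.epochs_per_night
    total_s = n_epochs * EPOCH_LENGTH_S
    n_samples = round(n_epochs * EPOCH_LENGTH_S * fs)
    t = np.arange(n_samples) / fs

    samples = np.zeros(n_samples)
    beat_times = []
    onset = 0.0
    while onset < total_s:
        epoch_idx = min(int(onset // EPOCH_LENGTH_S), n_epochs - 1)
        stage = hyp[epoch_idx]
        hr = rng.normal(config.mean_hr_bpm_per_stage[stage], config.hr_sd_bpm_per_stage[stage])
        hr = float(np.clip(hr, 30.5, 199.5))
        rr = 60.0 / hr
        # render the beat only on its local sample window
        lo = max(0, int((onset - 0.5 * rr) * fs))
        hi = min(n_samples, int((onset + 1.5 * rr) * fs) + 1)
        if hi > lo:
            samples[lo:hi] += _pulse_template(t[lo:hi], onset, rr)
        beat_times.append(onset + 0.30 * rr)
        onset += rr

    if config.baseline_wander_amp:
        samples += config.baseline_wander_amp * np.sin(
            2 * np.pi * config.baseline_wander_freq * t
        )
    if config.powerline_amp:
        samples += config.powerline_amp * np.sin(2 * np.pi * config.powerline_freq * t)
    if config.noise_sd:
        samples += rng.normal(0.0, config.noise_sd, n_samples)

    beats = np.array([bt for bt in beat_times if bt < total_s])
    return NightRecording(
        samples=samples,
        sampling_rate=fs,
        hypnogram=hyp,
        epoch_length_s=EPOCH_LENGTH_S,
        beat_times=beats,
    )


def ground_truth_rr(recording: NightRecording) -> list[np.ndarray]:
    """Per-epoch true inter-beat intervals (s) of a simulated recording.

    For each epoch, returns the successive differences of the simulator's
    systolic-peak times falling inside that epoch — the oracle against
    which the pulse-peak detector is validated.
    """
    if recording.beat_times is None:
        raise ValueError("recording carries no ground-truth beat times (not simulated?)")
    out = []
    for e in range(recording.n_epochs):
        lo, hi = e * recording.epoch_length_s, (e + 1) * recording.epoch_length_s
        in_epoch = recording.beat_times[(recording.beat_times >= lo) & (recording.beat_times < hi)]
        out.append(np.diff(in_epoch))
    return out


# ---------------------------------------------------------------------------
# File interchange

def write_recording_csv(recording: NightRecording, samples_path: str | Path,
                        hypnogram_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write samples as a one-column CSV, the hypnogram as (epoch_index,
    stage) CSV, and optionally a JSON sidecar with the sampling rate."""
    samples_path = Path(samples_path)
    with open(samples_path, "w") as fh:
        fh.write("ppg\n")
        np.savetxt(fh, recording.samples, fmt="%.10g")
    write_hypnogram_csv(recording.hypnogram, hypnogram_path)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "sampling_rate": recording.sampling_rate,
                    "epoch_length_s": recording.epoch_length_s,
                    "n_epochs": recording.n_epochs,
                },
                fh,
                indent=2,
            )


def write_hypnogram_csv(hypnogram: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch_index,stage\n")
        for i, stage in enumerate(hypnogram):
            fh.write(f"{i},{stage}\n")
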