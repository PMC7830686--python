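"""The synthetic night generator: determinism, geometry, beat-timing
ground truth, stage-dependent heart rates, and Markov-chain statistics."""

import numpy as np
import pytest
from scipy.stats import chisquare

from ppgsleep import SimulationConfig, detect_peaks, epochize, ground_truth_rr, simulate_night
from ppgsleep.synthetic import STAGES, SimulationError, simulate_hypnogram

from conftest import LOW_NOISE


def _constant_hr_config(bpm: float, **overrides):
    base = dict(
        sampling_rate=64.0,
        epochs_per_night=4,
        mean_hr_bpm_per_stage={s: bpm for s in STAGES},
        hr_sd_bpm_per_stage={s: 0.0 for s in STAGES},
        baseline_wander_amp=0.0,
        powerline_amp=0.0,
        noise_sd=0.0,
        seed=1,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def test_fixed_seed_is_bit_identical():
    a = simulate_night(SimulationConfig(epochs_per_night=6, seed=1, **LOW_NOISE))
    b = simulate_night(SimulationConfig(epochs_per_night=6, seed=1, **LOW_NOISE))
    assert np.array_equal(a.samples, b.samples)
    assert a.hypnogram == b.hypnogram


def test_sample_count_is_epochs_times_rate():
    rec = simulate_night(_constant_hr_config(60.0))
    assert len(rec.samples) == 4 * 30 * 64  # == 7680
    assert rec.n_epochs == 4


def test_non_stochastic_transition_matrix_rejected():
    bad = np.full((6, 6), 0.2)
    with pytest.raises(SimulationError, match="row-stochastic"):
        SimulationConfig(stage_transition_matrix=bad)


def test_heart_rate_out_of_range_rejected():
    with pytest.raises(SimulationError, match="30, 200"):
        SimulationConfig(mean_hr_bpm_per_stage={s: 250.0 for s in STAGES})


@pytest.mark.parametrize("bpm,expected_rr", [(60.0, 1.0), (120.0, 0.5)])
def test_ground_truth_rr_at_constant_rate(bpm, expected_rr):
    rec = simulate_night(_constant_hr_config(bpm))
    for rr in ground_truth_rr(rec):
        assert np.allclose(rr, expected_rr, atol=1e-12)


def test_noiseless_constant_rate_beats_detected_at_true_interval():
    """Clean 60-bpm night: detector recovers every beat at 1.0 s spacing
    (within one sample period)."""
    rec = simulate_night(_constant_hr_config(60.0))
    epochs = epochize(rec)
    for ep in epochs:
        beats = detect_peaks(ep)
        assert 29 <= len(beats) <= 31
        assert np.all(np.abs(np.diff(beats) - 1.0) <= 1.0 / rec.sampling_rate)


def test_epoch_mean_rr_matches_configured_rate(small_night):
    """Per-epoch mean of the simulator's own RR draws sits near 60/HR for
    that epoch's stage (within the configured beat-to-beat jitter)."""
    cfg_hr = {"W": 74.0, "S1": 70.0, "S2": 66.0, "S3": 62.0, "S4": 60.0, "REM": 72.0}
    for stage, rrs in zip(small_night.hypnogram, ground_truth_rr(small_night)):
        if len(rrs) < 10:
            continue
        expected = 60.0 / cfg_hr[stage]
        assert abs(np.mean(rrs) - expected) < 5 * 0.12 / np.sqrt(len(rrs))


def test_detected_stage_heart_rates_recover_configured_means():
    """Across >=50 low-noise epochs the detected per-stage heart rate is
    within 2 bpm of the configured stage means."""
    cfg = SimulationConfig(epochs_per_night=120, seed=11, **LOW_NOISE)
    rec = simulate_night(cfg)
    epochs = epochize(rec)
    assert len(epochs) >= 50
    by_stage: dict[str, list[float]] = {}
    for ep in epochs:
        beats = detect_peaks(ep)
        rr = np.diff(beats)
        rr = rr[(rr > 0.3) & (rr < 2.0)]
        if len(rr) < 4:
            continue
        by_stage.setdefault(ep.stage, []).append(60.0 / rr.mean())
    for stage, rates in by_stage.items():
        if len(rates) < 5:
            continue
        assert abs(np.mean(rates) - cfg.mean_hr_bpm_per_stage[stage]) < 2.0, stage


def test_transition_frequencies_match_configured_matrix():
    """Chi-square goodness of fit of empirical transition counts against
    the configured matrix is not rejected at alpha=0.01 (5000 epochs)."""
    cfg = SimulationConfig(epochs_per_night=5000, seed=5)
    hyp = simulate_hypnogram(cfg)
    P = cfg.stage_transition_matrix
    idx = {s: i for i, s in enumerate(STAGES)}
    counts = np.zeros((6, 6))
    for a, b in zip(hyp[:-1], hyp[1:]):
        counts[idx[a], idx[b]] += 1
    for i in range(6):
        n = counts[i].sum()
        if n < 50:
            continue
        support = P[i] > 0
        assert counts[i][~support].sum() == 0  # impossible transitions never occur
        _, p = chisquare(counts[i][support], n * P[i][support] / P[i][support].sum())
        assert p > 0.01, f"row {STAGES[i]}"


def test_recording_length_invariant_enforced():
    rec = simulate_night(_constant_hr_config(60.0))
    with pytest.raises(ValueError, match="sample count"):
        type(rec)(samples=rec.samples[:-1], sampling_rate=rec.sampling_rate,
                  hypnogram=rec.hypnogram)
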