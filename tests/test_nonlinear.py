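"""Nonlinear measures against frozen brute-force oracle values, closed-form
cases, and structural invariances."""

import math
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))
from oracles import (
    oracle_apen,
    oracle_fuzzyen,
    oracle_permen,
    oracle_recurrence,
    oracle_sampen,
)

from ppgsleep import (
    EntropyConfig,
    RecurrenceConfig,
    apen,
    fuzzyen,
    permen,
    recurrence_features,
    sampen,
)

# 15-point probe sequence (pi digits); oracle values frozen from the
# brute-force reference implementations at m=2, r=0.15*SD.
PROBE = np.array([3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5, 8, 9, 7, 9], dtype=float)
PROBE_APEN = -0.07410797215372167
PROBE_FUZZYEN = 2.080846618266357
# [4,7,9,10,6,11,3], order 3: patterns (012)x2, (201)x2, (102)x1
PERMEN_EXAMPLE = 1.0549201679861442


def test_apen_matches_frozen_oracle_value():
    assert apen(PROBE) == pytest.approx(PROBE_APEN, abs=1e-12)


def test_sampen_probe_has_no_matches_and_returns_sentinel():
    """At 15 points and r=0.15 SD no template pairs match: the defined
    sentinel is +inf, and the oracle agrees."""
    assert math.isinf(sampen(PROBE))
    assert math.isinf(oracle_sampen(PROBE, 2, 0.15 * np.std(PROBE)))


def test_fuzzyen_matches_frozen_oracle_value():
    assert fuzzyen(PROBE) == pytest.approx(PROBE_FUZZYEN, abs=1e-12)


def test_permen_matches_hand_enumerated_patterns():
    assert permen(np.array([4, 7, 9, 10, 6, 11, 3.0]), order=3, delay=1) == pytest.approx(
        PERMEN_EXAMPLE, abs=1e-12
    )


def test_all_measures_agree_with_bruteforce_on_random_series():
    """Direct-count oracles and optimized kernels agree to 1e-10 on random
    series of length 50-200."""
    rng = np.random.default_rng(123)
    for _ in range(25):
        n = int(rng.integers(50, 201))
        u = rng.normal(size=n)
        r = 0.15 * np.std(u)
        assert abs(apen(u) - oracle_apen(u, 2, r)) < 1e-10
        s_impl, s_orc = sampen(u), oracle_sampen(u, 2, r)
        assert (math.isinf(s_impl) and math.isinf(s_orc)) or abs(s_impl - s_orc) < 1e-10
        assert abs(fuzzyen(u) - oracle_fuzzyen(u, 2, r)) < 1e-10
        assert abs(permen(u) - oracle_permen(u, 3)) < 1e-10
        rr_i, det_i = recurrence_features(u)
        rr_o, det_o = oracle_recurrence(u, 2, 1, r, 2)
        assert abs(rr_i - rr_o) < 1e-10 and abs(det_i - det_o) < 1e-10


def test_constant_series_closed_forms():
    u = np.full(100, 7.0)
    assert apen(u) == 0.0
    assert sampen(u) == pytest.approx(0.0, abs=1e-12)
    assert fuzzyen(u) == 0.0
    rr, det = recurrence_features(u)
    n = 99  # embedded points at m=2
    assert rr == 1.0
    # the two single-cell corner diagonals can never reach lmin=2
    assert det == pytest.approx((n * n - n - 2) / (n * n - n), abs=1e-12)


def test_monotone_series_has_zero_permutation_entropy():
    assert permen(np.arange(50.0)) == 0.0


def test_alternating_series_order_two_gives_ln2():
    u = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0])
    assert permen(u, order=2) == pytest.approx(math.log(2), abs=1e-12)


def test_permutation_ties_broken_by_subscript():
    # all values equal: stable ranking gives the identity pattern only
    assert permen(np.zeros(20), order=3) == 0.0


def test_iid_noise_with_tiny_epsilon_has_near_zero_recurrence():
    rng = np.random.default_rng(1)
    u = rng.normal(size=200)
    rr, _ = recurrence_features(
        u, RecurrenceConfig(m=2, delay=1, epsilon=1e-6, mode="absolute", lmin=2)
    )
    assert rr < 0.001


def test_recurrence_on_coarse_sine_matches_oracle():
    t = np.arange(20)
    s = np.sin(2 * np.pi * t / 8)  # 8 samples per period
    eps = 0.30 * np.std(s)
    cfg = RecurrenceConfig(m=2, delay=1, epsilon=eps, mode="absolute", lmin=2)
    rr, det = recurrence_features(s, cfg)
    assert rr == pytest.approx(0.08187134502923976, abs=1e-12)
    assert det == pytest.approx(1.0, abs=1e-12)


def test_affine_invariance_in_sd_fraction_mode():
    rng = np.random.default_rng(9)
    u = rng.normal(size=150)
    for a, b in [(3.0, 5.0), (0.25, -2.0)]:
        assert apen(a * u + b) == pytest.approx(apen(u), abs=1e-9)
        assert sampen(a * u + b) == pytest.approx(sampen(u), abs=1e-9)
        assert fuzzyen(a * u + b) == pytest.approx(fuzzyen(u), abs=1e-9)


def test_sampen_reversal_invariance():
    rng = np.random.default_rng(2)
    u = rng.normal(size=120)
    assert sampen(u[::-1].copy()) == pytest.approx(sampen(u), abs=1e-12)


def test_fuzzyen_offset_invariance():
    # mathematically exact (mean-centering removes the offset); in floats
    # the centering subtraction leaves rounding at the last few digits
    rng = np.random.default_rng(4)
    u = rng.normal(size=100)
    cfg = EntropyConfig(m=2, r=0.2, mode="absolute")
    assert fuzzyen(u + 1000.0, cfg) == pytest.approx(fuzzyen(u, cfg), rel=1e-9)


def test_bounds_and_validation():
    rng = np.random.default_rng(8)
    u = rng.normal(size=100)
    rr, det = recurrence_features(u)
    assert 0 <= rr <= 1 and 0 <= det <= 1
    with pytest.raises(ValueError, match="at least"):
        apen(np.array([1.0, 2.0, 3.0]))
    with pytest.raises(ValueError, match="order"):
        permen(u, order=1)
    with pytest.raises(ValueError, match="epsilon"):
        RecurrenceConfig(epsilon=-1.0)
    with pytest.raises(ValueError, match="sd_fraction"):
        EntropyConfig(r=1.5)
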