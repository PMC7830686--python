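"""Nonlinear regularity features of a short physiological time series.

Six measures suitable for 30-s windows: approximate entropy (ApEn), sample
entropy (SampEn), fuzzy entropy (FuzzyEn), permutation entropy (PerEn), and
two recurrence-plot statistics — recurrence rate (RR) and determinism
(DET).

Conventions, stated explicitly because the literature varies:

* All template/vector distances are Chebyshev (maximum coordinate
  difference), including in the recurrence plot.
* ApEn includes self-matches (Pincus's original definition); SampEn and
  FuzzyEn exclude them.
* SampEn averages the per-template fraction of matching templates over all
  N−m+1 templates of length m (and all N−m of length m+1), so a perfectly
  regular series scores exactly 0 and the statistic is invariant to
  sequence reversal.
* FuzzyEn mean-centers each embedded vector and uses the Gaussian
  membership exp(−ln2·(d/r)²), so it is exactly invariant to constant
  offsets.
* The tolerance r (and the recurrence threshold ε) default to a fraction
  of the series SD, making the entropies invariant to positive affine
  rescaling.
* Permutation patterns break ties by subscript order (stable ranking).
* The recurrence main diagonal (line of identity) is excluded from both RR
  and DET; DET counts points on diagonal lines of length ≥ lmin.

All entropies are reported in nats.  SampEn with no matches at either
template length returns ``inf`` (a flagged sentinel, not an exception);
callers that need finite features substitute it downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_CHUNK = 512  # row-block size for pairwise distance accumulation


@dataclass(frozen=True)
class EntropyConfig:
    """Embedding dimension and tolerance for Ap/Samp/FuzzyEn.

    With ``mode="sd_fraction"`` the effective tolerance is ``r`` times the
    population SD of the series (the conventional choice, default 0.15 SD
    with m = 2); ``mode="absolute"`` uses ``r`` in signal units.
    """

    m: int = 2
    r: float = 0.15
    mode: str = "sd_fraction"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.mode not in ("absolute", "sd_fraction"):
            raise ValueError("mode must be 'absolute' or 'sd_fraction'")
        if self.mode == "absolute" and self.r <= 0:
            raise ValueError("absolute tolerance r must be positive")
        if self.mode == "sd_fraction" and not 0 < self.r <= 1:
            raise ValueError("sd_fraction tolerance r must lie in (0, 1]")

    def resolve_r(self, u: np.ndarray) -> float:
        if self.mode == "absolute":
            return self.r
        return self.r * float(np.std(u))


@dataclass(frozen=True)
class RecurrenceConfig:
    """Recurrence-plot embedding and thresholding parameters."""

    m: int = 2
    delay: int = 1
    epsilon: float = 0.15
    mode: str = "sd_fraction"
    lmin: int = 2

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.lmin < 2:
            raise ValueError("lmin must be >= 2")
        if self.m < 1 or self.delay < 1:
            raise ValueError("m and delay must be >= 1")
        if self.mode not in ("absolute", "sd_fraction"):
            raise ValueError("mode must be 'absolute' or 'sd_fraction'")

    def resolve_epsilon(self, u: np.ndarray) -> float:
        if self.mode == "absolute":
            return self.epsilon
        return self.epsilon * float(np.std(u))


def _embed(u: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    n = len(u) - (m - 1) * delay
    if n < 1:
        raise ValueError(f"series of length {len(u)} too short for m={m}, delay={delay}")
    idx = np.arange(n)[:, None] + delay * np.arange(m)[None, :]
    return u[idx]


def _scalar_match_matrix(u: np.ndarray, r: float) -> np.ndarray:
    """Boolean matrix B[i, j] = |u_i − u_j| <= r, built in row blocks."""
    n = len(u)
    B = np.empty((n, n), dtype=bool)
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        B[lo:hi] = np.abs(u[lo:hi, None] - u[None, :]) <= r
    return B


def _template_match_matrix(B: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    """Chebyshev template matches from the scalar match matrix.

    Embedded vectors X_i = (u_i, u_{i+delay}, …) match within r iff every
    coordinate pair matches, i.e. the AND of m shifted diagonal blocks of B.
    """
    n = len(B) - (m - 1) * delay
    C = B[:n, :n].copy()
    for k in range(1, m):
        o = k * delay
        C &= B[o : o + n, o : o + n]
    return C


def _chebyshev_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Chebyshev distances via an incremental column-wise maximum
    (avoids materializing the (n, n, m) difference tensor)."""
    D = np.abs(X[:, 0, None] - X[None, :, 0])
    for k in range(1, X.shape[1]):
        np.maximum(D, np.abs(X[:, k, None] - X[None, :, k]), out=D)
    return D


def _check_length(u: np.ndarray, m: int) -> None:
    if len(u) < m + 2:
        raise ValueError(f"series must have at least m + 2 = {m + 2} samples, got {len(u)}")


def apen(u: np.ndarray, cfg: EntropyConfig | None = None) -> float:
    """Approximate entropy (nats).

    Φ^m(r) is the mean of ln C_i^m(r), where C_i^m is the fraction of
    templates (self-match included) within Chebyshev distance r of template
    i; ApEn = Φ^m − Φ^{m+1}.  A constant series scores exactly 0.
    """
    if cfg is None:
        cfg = EntropyConfig()
    u = np.asarray(u, dtype=float)
    _check_length(u, cfg.m)
    r = cfg.resolve_r(u)
    B = _scalar_match_matrix(u, r)

    def phi(mm: int) -> float:
        C = _template_match_matrix(B, mm)
        c = C.sum(axis=1) / len(C)
        return float(np.mean(np.log(c)))

    return phi(cfg.m) - phi(cfg.m + 1)


def sampen(u: np.ndarray, cfg: EntropyConfig | None = None) -> float:
    """Sample entropy −ln(A/B) (nats); self-matches excluded.

    B is the mean, over all N−m+1 templates of length m, of the fraction of
    other templates within Chebyshev distance r; A is the same quantity at
    length m+1.  Returns ``inf`` (flagged sentinel) when either count is
    zero — a perfectly regular series instead scores exactly 0 (A/B = 1).
    """
    if cfg is None:
        cfg = EntropyConfig()
    u = np.asarray(u, dtype=float)
    _check_length(u, cfg.m)
    r = cfg.resolve_r(u)
    Bmat = _scalar_match_matrix(u, r)

    def mean_match_fraction(mm: int) -> float:
        C = _template_match_matrix(Bmat, mm)
        n = len(C)
        return float((int(C.sum()) - n) / (n * (n - 1)))  # self-matches removed

    B = mean_match_fraction(cfg.m)
    A = mean_match_fraction(cfg.m + 1)
    if A <= 0 or B <= 0:
        logger.debug("sampen: no template matches (A=%g, B=%g) — sentinel inf", A, B)
        return math.inf
    return -math.log(A / B)


def _fuzzy_phi(u: np.ndarray, m: int, r: float) -> float:
    X = _embed(u, m)
    X = X - X.mean(axis=1, keepdims=True)
    n = len(X)
    D = _chebyshev_distance_matrix(X)
    np.square(D, out=D)
    D *= -math.log(2.0) / r**2
    np.exp(D, out=D)
    total = D.sum(axis=1) - 1.0  # drop the self-similarity term
    return float(np.mean(total / (n - 1)))


def fuzzyen(u: np.ndarray, cfg: EntropyConfig | None = None) -> float:
    """Fuzzy entropy ln Φ^m − ln Φ^{m+1} (nats).

    Each embedded vector is centered on its own mean, and pairwise
    similarity is the Gaussian membership exp(−ln2·(d/r)²) of the Chebyshev
    distance d, averaged excluding self-pairs.
    """
    if cfg is None:
        cfg = EntropyConfig()
    u = np.asarray(u, dtype=float)
    _check_length(u, cfg.m)
    r = cfg.resolve_r(u)
    if r <= 0:
        return 0.0  # constant series: every vector identical after centering
    return math.log(_fuzzy_phi(u, cfg.m, r)) - math.log(_fuzzy_phi(u, cfg.m + 1, r))


def permen(u: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Permutation entropy (nats) of ordinal patterns of embedded windows.

    Each window of ``order`` values (spaced by ``delay``) is reduced to the
    permutation that sorts it ascending, ties broken by subscript order
    (stable sort); the result is the Shannon entropy of the empirical
    pattern distribution.  A monotone series scores 0.
    """
    if order < 2:
        raise ValueError("order must be >= 2")
    u = np.asarray(u, dtype=float)
    if len(u) < (order - 1) * delay + 2:
        raise ValueError(
            f"series must have at least (order-1)*delay + 2 = {(order - 1) * delay + 2} samples"
        )
    X = _embed(u, order, delay)
    patterns = np.argsort(X, axis=1, kind="stable")
    radix = order ** np.arange(order)
    codes = patterns @ radix
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def recurrence_features(u: np.ndarray, cfg: RecurrenceConfig | None = None) -> tuple[float, float]:
    """Recurrence rate and determinism of the thresholded recurrence plot.

    The plot marks embedded-vector pairs within Chebyshev distance ε; the
    main diagonal is excluded.  Recurrence rate is the fraction of marked
    off-diagonal pairs; determinism is the fraction of marked points lying
    on diagonal line segments of length ≥ lmin.  Both lie in [0, 1].

    Note the two single-element corner diagonals can never reach lmin, so
    even a constant series has DET = 1 − 2/(n²−n), i.e. 1 up to O(n⁻²).
    """
    if cfg is None:
        cfg = RecurrenceConfig()
    u = np.asarray(u, dtype=float)
    min_len = (cfg.m - 1) * cfg.delay + cfg.lmin + 1
    if len(u) < min_len:
        raise ValueError(f"series must have at least {min_len} samples for these settings")
    eps = cfg.resolve_epsilon(u)  # 0 for a constant series: exact matches still recur
    R = _template_match_matrix(_scalar_match_matrix(u, eps), cfg.m, cfg.delay)
    n = len(R)
    np.fill_diagonal(R, False)

    total = int(R.sum())
    rr = total / (n * (n - 1))
    if total == 0:
        return 0.0, 0.0

    on_lines = 0
    for k in range(-(n - 1), n):
        if k == 0:
            continue
        diag = np.diagonal(R, offset=k)
        if not diag.any():
            continue
        # run lengths of consecutive True values
        padded = np.concatenate(([False], diag, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        runs = edges[1::2] - edges[::2]
        on_lines += int(runs[runs >= cfg.lmin].sum())
    det = on_lines / total
    return float(rr), float(det)
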