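"""The 11 time-domain features of one PPG epoch.

Median, extrema, range, mean, population variance, standardized skewness
and (non-excess) kurtosis, and three difference-entropy features: the
Shannon entropy (nats, 100-bin histogram) of the first- and second-order
difference sequences and their ratio.  The histogram bin count is fixed so
the entropy values are deterministic and comparable across epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

from ppgsleep.preprocess import EpochSignal

logger = logging.getLogger(__name__)

N_ENTROPY_BINS = 100


@dataclass
class TimeFeatures:
    med: float
    max: float
    min: float
    dif: float
    var: float
    ske: float
    kur: float
    mean: float
    en1st: float
    en2nd: float
    en1st_2nd: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def difference_entropy(x: np.ndarray, order: int = 1, bins: int = N_ENTROPY_BINS) -> float:
    """Shannon entropy (nats) of a fixed-bin histogram of the order-th
    difference sequence of x.  A constant difference sequence occupies a
    single bin and scores 0."""
    d = np.diff(np.asarray(x, dtype=float), n=order)
    if len(d) == 0 or np.ptp(d) == 0:
        return 0.0
    counts, _ = np.histogram(d, bins=bins, range=(d.min(), d.max()))
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def time_features(epoch: EpochSignal | np.ndarray) -> TimeFeatures:
    """Compute all 11 time-domain features of one epoch.

    Degenerate cases: a constant epoch has undefined skewness/kurtosis,
    which are returned as 0 with a logged flag, and a zero second-order
    difference entropy makes the entropy ratio 0 (also flagged).
    """
    z = epoch.samples if isinstance(epoch, EpochSignal) else np.asarray(epoch, dtype=float)
    if len(z) < 3:
        raise ValueError("need at least 3 samples for time-domain features")
    if not np.all(np.isfinite(z)):
        raise ValueError("samples must be finite")

    m = float(np.mean(z))
    var = float(np.mean((z - m) ** 2))  # population (1/n) variance
    if var > 0:
        sd = np.sqrt(var)
        ske = float(np.mean((z - m) ** 3) / sd**3)
        kur = float(np.mean((z - m) ** 4) / sd**4)
    else:
        logger.debug("constant epoch: skewness/kurtosis undefined, set to 0")
        ske = kur = 0.0

    en1 = difference_entropy(z, order=1)
    en2 = difference_entropy(z, order=2)
    if en2 > 0:
        ratio = en1 / en2
    else:
        logger.debug("second-difference entropy is 0: entropy ratio set to 0")
        ratio = 0.0

    return TimeFeatures(
        med=float(np.median(z)),
        max=float(np.max(z)),
        min=float(np.min(z)),
        dif=float(np.max(z) - np.min(z)),
        var=var,
        ske=ske,
        kur=kur,
        mean=m,
        en1st=en1,
        en2nd=en2,
        en1st_2nd=ratio,
    )
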