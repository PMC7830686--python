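"""Published reference confusion matrices for single-channel PPG sleep
staging, at 3-, 4- and 5-class granularity.

These count matrices (rows = clinician-scored truth, columns = model
prediction) come from a published clinical evaluation on the CAP sleep
database and serve as fixed inputs for validating the metrics engine: the
package recomputes accuracy, Cohen's kappa and the per-class indices from
the raw counts.

Known typesetting quirk in the source tables: the 4-class REM precision is
printed as 0.86, but the printed counts give 289/369 ≈ 0.78 (and the
printed F1 of 0.77 is consistent with 0.78, not 0.86); the printed value is
therefore treated as an error and excluded from comparisons.
"""

from __future__ import annotations

import numpy as np

from ppgsleep.metrics import ConfusionMatrix

THREE_CLASS = ConfusionMatrix(
    classes=("W", "NREM", "REM"),
    counts=np.array(
        [
            [342, 36, 14],
            [51, 353, 14],
            [26, 24, 340],
        ]
    ),
)

FOUR_CLASS = ConfusionMatrix(
    classes=("W", "LS", "SWS", "REM"),
    counts=np.array(
        [
            [360, 25, 20, 6],
            [36, 276, 40, 34],
            [25, 48, 308, 40],
            [21, 43, 29, 289],
        ]
    ),
)

FIVE_CLASS = ConfusionMatrix(
    classes=("W", "N1", "N2", "N3", "REM"),
    counts=np.array(
        [
            [193, 1, 11, 14, 11],
            [11, 38, 7, 16, 22],
            [13, 4, 156, 21, 10],
            [12, 1, 39, 156, 13],
            [18, 7, 17, 23, 160],
        ]
    ),
)

BENCHMARKS: dict[str, ConfusionMatrix] = {
    "three": THREE_CLASS,
    "four": FOUR_CLASS,
    "five": FIVE_CLASS,
}

#: The published summary indices (accuracy to 4 decimals, kappa to 2) and
#: per-class precision/recall/F1 to 2 decimals, as printed in the source
#: tables.  ``None`` marks the documented 4-class REM precision print error.
PUBLISHED = {
    "three": {
        "accuracy": 0.8625,
        "kappa": 0.79,
        "per_class": {
            "W": {"precision": 0.82, "recall": 0.87, "f1": 0.84},
            "NREM": {"precision": 0.85, "recall": 0.84, "f1": 0.85},
            "REM": {"precision": 0.92, "recall": 0.87, "f1": 0.90},
        },
    },
    "four": {
        "accuracy": 0.7706,
        "kappa": 0.69,
        "per_class": {
            "W": {"precision": 0.81, "recall": 0.88, "f1": 0.84},
            "LS": {"precision": 0.70, "recall": 0.72, "f1": 0.71},
            "SWS": {"precision": 0.78, "recall": 0.73, "f1": 0.75},
            "REM": {"precision": None, "recall": 0.76, "f1": 0.77},
        },
    },
    "five": {
        "accuracy": 0.7217,
        "kappa": 0.64,
        "per_class": {
            "W": {"precision": 0.78, "recall": 0.84, "f1": 0.81},
            "N1": {"precision": 0.75, "recall": 0.40, "f1": 0.52},
            "N2": {"precision": 0.68, "recall": 0.76, "f1": 0.72},
            "N3": {"precision": 0.68, "recall": 0.71, "f1": 0.69},
            "REM": {"precision": 0.74, "recall": 0.71, "f1": 0.73},
        },
    },
}
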