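"""Stage-label schemes: 6-class R&K annotations remapped to 5/4/3 classes,
plus class balancing by random undersampling.

The merges follow standard sleep-medicine convention: the five-class (AASM)
scheme merges S3+S4 into N3; the four-class scheme groups S1+S2 as light
sleep (LS) and S3+S4 as slow-wave sleep (SWS); the three-class scheme
collapses all of S1–S4 into NREM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

SIX_STAGES = ("W", "S1", "S2", "S3", "S4", "REM")

# Accepted spellings of the six R&K stages; anything else is unscored.
_STAGE_ALIASES = {
    "W": "W", "WAKE": "W", "0": "W",
    "S1": "S1", "1": "S1", "N1": "S1",
    "S2": "S2", "2": "S2", "N2": "S2",
    "S3": "S3", "3": "S3", "N3": "S3",
    "S4": "S4", "4": "S4", "N4": "S4",
    "REM": "REM", "R": "REM", "5": "REM",
}


def normalize_stage(label: object) -> str | None:
    """Map a raw annotation to one of the six R&K labels, or None if the
    label is unrecognized (e.g. MT / movement time → unscored)."""
    if label is None:
        return None
    return _STAGE_ALIASES.get(str(label).strip().upper())


@dataclass(frozen=True)
class StageScheme:
    """A named staging vocabulary and its total mapping from the six R&K
    stages onto it."""

    name: str
    classes: tuple[str, ...]
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(SIX_STAGES) - set(self.mapping)
        if missing:
            raise ValueError(f"mapping must cover all six stages; missing {sorted(missing)}")
        if set(self.mapping.values()) - set(self.classes):
            raise ValueError("mapping targets must be scheme classes")

    @property
    def n_classes(self) -> int:
        return len(self.classes)


SCHEMES: dict[str, StageScheme] = {
    "six": StageScheme("six", SIX_STAGES, {s: s for s in SIX_STAGES}),
    "five": StageScheme(
        "five",
        ("W", "N1", "N2", "N3", "REM"),
        {"W": "W", "S1": "N1", "S2": "N2", "S3": "N3", "S4": "N3", "REM": "REM"},
    ),
    "four": StageScheme(
        "four",
        ("W", "LS", "SWS", "REM"),
        {"W": "W", "S1": "LS", "S2": "LS", "S3": "SWS", "S4": "SWS", "REM": "REM"},
    ),
    "three": StageScheme(
        "three",
        ("W", "NREM", "REM"),
        {"W": "W", "S1": "NREM", "S2": "NREM", "S3": "NREM", "S4": "NREM", "REM": "REM"},
    ),
}

_BY_N = {s.n_classes: s for s in SCHEMES.values()}


def scheme_for(n_classes: int) -> StageScheme:
    """Look up the scheme with the given class count (3, 4, 5 or 6)."""
    try:
        return _BY_N[int(n_classes)]
    except KeyError:
        raise ValueError(f"no staging scheme with {n_classes} classes") from None


def remap(hypnogram: Sequence[str], scheme: StageScheme | int) -> list[str]:
    """Element-wise remap of a 6-class hypnogram into ``scheme``'s labels.

    Raises if any entry is not a valid six-stage label, listing the
    offending epoch indices.
    """
    if isinstance(scheme, int):
        scheme = scheme_for(scheme)
    bad = [i for i, s in enumerate(hypnogram) if s not in scheme.mapping]
    if bad:
        shown = bad[:10]
        raise ValueError(
            f"unknown stage label(s) at epoch(s) {shown}"
            + ("…" if len(bad) > len(shown) else "")
        )
    return [scheme.mapping[s] for s in hypnogram]


def balance(
    features: pd.DataFrame | np.ndarray | Sequence,
    labels: Sequence[str],
    seed: int = 0,
):
    """Random undersampling of every class to the minority-class count.

    Returns ``(features_subset, labels_subset, indices)`` where ``indices``
    are the retained positions, in their original order.  Deterministic for
    a fixed seed.
    """
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("no epochs to balance")
    classes, counts = np.unique(labels, return_counts=True)
    n_min = counts.min()
    if n_min == 0:
        raise ValueError("balance requires at least one epoch per class")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    indices = np.sort(np.concatenate(keep))
    sub_labels = labels[indices]
    if isinstance(features, pd.DataFrame):
        sub_features = features.iloc[indices]
    else:
        sub_features = np.asarray(features)[indices]
    return sub_features, list(sub_labels), indices
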