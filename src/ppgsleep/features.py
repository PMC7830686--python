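"""Assembly of the 21-feature vector for each epoch.

11 time-domain features + 4 HRV band powers + 6 nonlinear measures, with
the canonical column names used throughout the feature tables.  Non-finite
sentinel values (e.g. a SampEn with no template matches) are substituted
with 0 and flagged, so downstream classifiers always see finite inputs.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from ppgsleep.hrv_features import BandDefinition, hrv_features
from ppgsleep.nonlinear_features import (
    EntropyConfig,
    RecurrenceConfig,
    apen,
    fuzzyen,
    permen,
    recurrence_features,
    sampen,
)
from ppgsleep.preprocess import EpochSignal
from ppgsleep.time_features import time_features

logger = logging.getLogger(__name__)

TIME_FEATURE_NAMES: tuple[str, ...] = (
    "Med_PPG",
    "Max_PPG",
    "Min_PPG",
    "Dif_PPG",
    "Var_PPG",
    "Ske_PPG",
    "Kur_PPG",
    "Mean_PPG",
    "En1st_PPG",
    "En2nd_PPG",
    "En1st_2nd_PPG",
)
HRV_FEATURE_NAMES: tuple[str, ...] = ("LF_power", "TLF_power", "HF_power", "MF_power")
NONLINEAR_FEATURE_NAMES: tuple[str, ...] = (
    "ApEn",
    "SampEn",
    "FuzzyEn",
    "PerEn",
    "DET",
    "RecurrenceRate",
)
#: All 21 feature names, in table order.
FEATURE_NAMES: tuple[str, ...] = TIME_FEATURE_NAMES + HRV_FEATURE_NAMES + NONLINEAR_FEATURE_NAMES

_TIME_KEY_ORDER = ("med", "max", "min", "dif", "var", "ske", "kur", "mean", "en1st", "en2nd", "en1st_2nd")


def extract_epoch_features(
    epoch: EpochSignal,
    entropy_cfg: EntropyConfig | None = None,
    recurrence_cfg: RecurrenceConfig | None = None,
    bands: BandDefinition | None = None,
    permen_order: int = 3,
    permen_delay: int = 1,
) -> dict[str, float]:
    """Compute the full 21-feature dictionary for one epoch.

    The nonlinear measures operate on the (denoised) PPG samples of the
    epoch itself; the HRV band powers operate on the RR tachogram derived
    from detected pulse peaks.
    """
    if entropy_cfg is None:
        entropy_cfg = EntropyConfig()
    if recurrence_cfg is None:
        recurrence_cfg = RecurrenceConfig()

    tf = time_features(epoch).as_dict()
    out: dict[str, float] = {
        name: tf[key] for name, key in zip(TIME_FEATURE_NAMES, _TIME_KEY_ORDER)
    }

    hrv = hrv_features(epoch, bands)
    out["LF_power"] = hrv.lf_power
    out["TLF_power"] = hrv.tlf_power
    out["HF_power"] = hrv.hf_power
    out["MF_power"] = hrv.mf_power

    u = epoch.samples
    out["ApEn"] = apen(u, entropy_cfg)
    out["SampEn"] = sampen(u, entropy_cfg)
    out["FuzzyEn"] = fuzzyen(u, entropy_cfg)
    out["PerEn"] = permen(u, order=permen_order, delay=permen_delay)
    rr, det = recurrence_features(u, recurrence_cfg)
    out["DET"] = det
    out["RecurrenceRate"] = rr

    for name, value in out.items():
        if not np.isfinite(value):
            logger.debug("epoch %s: non-finite %s substituted with 0", epoch.epoch_index, name)
            out[name] = 0.0
    return out


def extract_feature_table(
    epochs: Iterable[EpochSignal],
    entropy_cfg: EntropyConfig | None = None,
    recurrence_cfg: RecurrenceConfig | None = None,
    bands: BandDefinition | None = None,
    subject_id: str | None = None,
) -> pd.DataFrame:
    """Feature table for a list of epochs: one row per epoch with
    ``epoch_index``, ``stage`` (and optionally ``subject_id``) identifier
    columns followed by the 21 feature columns."""
    rows = []
    for ep in epochs:
        row: dict[str, object] = {"epoch_index": ep.epoch_index, "stage": ep.stage}
        if subject_id is not None:
            row["subject_id"] = subject_id
        row.update(
            extract_epoch_features(ep, entropy_cfg, recurrence_cfg, bands)
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) == 0:
        raise ValueError("no epochs to extract features from")
    return df


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """The 21 feature columns of a feature table, in canonical order."""
    missing = [n for n in FEATURE_NAMES if n not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    return table.loc[:, list(FEATURE_NAMES)]


def stage_labels(table: pd.DataFrame) -> list[str]:
    return list(table["stage"].astype(str))
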