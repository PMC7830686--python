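"""Standardization (no leakage), cross-validation partitioning,
determinism, and feature-order invariance of the staging classifier."""

import numpy as np
import pandas as pd
import pytest

from ppgsleep import CvPlan, cross_validate, standardize
from ppgsleep.features import FEATURE_NAMES


def make_separable_table(n=120, seed=0):
    """Three linearly separated classes over the 21 canonical features."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(["W", "NREM", "REM"], n // 3)
    shift = {"W": 0.0, "NREM": 3.0, "REM": 6.0}
    X = rng.normal(size=(n, len(FEATURE_NAMES)))
    X[:, 0] += [shift[s] for s in labels]
    X[:, 1] -= [shift[s] for s in labels]
    return pd.DataFrame(X, columns=FEATURE_NAMES), labels


def test_standardize_uses_train_statistics_only():
    train = np.array([[8.0], [12.0]])  # mean 10, sd 2
    z, scaler = standardize(train, np.array([[14.0]]))
    assert z[0, 0] == pytest.approx(2.0)
    # a disjoint test distribution is not re-centered on itself
    far = scaler.transform(np.array([[110.0]]))
    assert far[0, 0] == pytest.approx(50.0)


def test_standardized_train_has_zero_mean_unit_sd():
    rng = np.random.default_rng(1)
    X = rng.normal(5, 3, size=(200, 4))
    z, _ = standardize(X)
    assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
    assert np.allclose(z.std(axis=0), 1, atol=1e-12)


def test_zero_spread_feature_passed_through():
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    z, _ = standardize(X)
    assert np.allclose(z[:, 0], 1.0)  # unscaled, not NaN


def test_every_epoch_predicted_exactly_once():
    X, y = make_separable_table(100 + 20)
    result = cross_validate(X, y, CvPlan(k=5, seed=0))
    assert len(result.predictions) == len(y)
    assert np.all(result.fold_assignment >= 0)
    assert result.confusion.total == len(y)
    # each fold holds roughly 1/5 of the data
    _, counts = np.unique(result.fold_assignment, return_counts=True)
    assert len(counts) == 5


def test_separable_classes_are_recovered():
    X, y = make_separable_table(150)
    result = cross_validate(X, y, CvPlan(k=5, seed=0))
    acc = np.mean(result.predictions == result.true)
    assert acc > 0.9


def test_fixed_seed_reproduces_folds_and_matrix():
    X, y = make_separable_table(90)
    a = cross_validate(X, y, CvPlan(k=5, seed=3))
    b = cross_validate(X, y, CvPlan(k=5, seed=3))
    assert np.array_equal(a.fold_assignment, b.fold_assignment)
    assert np.array_equal(a.confusion.counts, b.confusion.counts)


def test_feature_column_order_does_not_change_predictions():
    X, y = make_separable_table(90)
    shuffled = X[list(reversed(X.columns))]
    a = cross_validate(X, y, CvPlan(k=5, seed=3))
    b = cross_validate(shuffled, y, CvPlan(k=5, seed=3))
    assert np.array_equal(a.predictions, b.predictions)


def test_leave_one_subject_out_requires_and_uses_groups():
    X, y = make_separable_table(90)
    with pytest.raises(ValueError, match="groups"):
        cross_validate(X, y, CvPlan(strategy="leave_one_subject_out"))
    groups = np.repeat(["s1", "s2", "s3"], 30)
    result = cross_validate(X, y, CvPlan(strategy="leave_one_subject_out"), groups=groups)
    # one fold per subject, and no subject's epochs are split across folds
    for g in np.unique(groups):
        assert len(set(result.fold_assignment[groups == g])) == 1


def test_missing_class_in_fold_warns_but_completes():
    X, y = make_separable_table(90)
    y = np.array(y, dtype=object)
    y[0] = "RARE"  # a singleton class is absent from its own fold's training split
    with pytest.warns(UserWarning, match="missing a class"):
        result = cross_validate(X, list(y), CvPlan(k=5, seed=0))
    assert result.confusion.total == len(y)


def test_plan_validation():
    with pytest.raises(ValueError, match="k >= 2"):
        CvPlan(k=1)
    with pytest.raises(ValueError, match="strategy"):
        CvPlan(strategy="bootstrap")
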