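import numpy as np
import pandas as pd
import pytest

from eegscreen.classify import (
    compute_metrics,
    confusion,
    cross_validate,
    smote,
    train_svm_rbf,
)


def _clusters(rng, counts, centers, spread=0.3):
    X, y = [], []
    for (label, n), c in zip(counts.items(), centers):
        X.append(rng.normal(c, spread, size=(n, len(c))))
        y.extend([label] * n)
    return np.vstack(X), np.array(y)


# --- SMOTE -----------------------------------------------------------------


def test_smote_balanced_input_unchanged(rng):
    X, y = _clusters(rng, {"a": 10, "b": 10}, [(0, 0), (5, 5)])
    Xb, yb = smote(X, y, seed=0)
    assert np.array_equal(Xb, X)
    assert np.array_equal(yb, y)


def test_smote_equalizes_study_counts(rng):
    """The study's 10/33/77 imbalance becomes 77/77/77."""
    X, y = _clusters(rng, {"dem": 10, "mci": 33, "ctl": 77}, [(0, 0), (4, 0), (0, 4)])
    Xb, yb = smote(X, y, k_neighbors=5, seed=1)
    counts = pd.Series(yb).value_counts()
    assert counts.to_dict() == {"dem": 77, "mci": 77, "ctl": 77}
    assert Xb.shape[0] == 231


def test_smote_points_are_convex_combinations(rng):
    """Every synthetic point lies on a segment between two same-class
    originals (checked geometrically in 2-D)."""
    X, y = _clusters(rng, {"a": 8, "b": 20}, [(0, 0), (10, 10)], spread=1.0)
    Xb, yb = smote(X, y, k_neighbors=3, seed=2)
    synth = Xb[len(y):]
    labels = yb[len(y):]
    originals = {cls: X[y == cls] for cls in np.unique(y)}
    for pt, cls in zip(synth, labels):
        O = originals[cls]
        ok = False
        for i in range(len(O)):
            for j in range(len(O)):
                if i == j:
                    continue
                d = O[j] - O[i]
                denom = d @ d
                if denom == 0:
                    continue
                t = (pt - O[i]) @ d / denom
                if -1e-9 <= t <= 1 + 1e-9 and np.linalg.norm(O[i] + t * d - pt) < 1e-8:
                    ok = True
                    break
            if ok:
                break
        assert ok, f"synthetic point {pt} is not on any same-class segment"


def test_smote_determinism(rng):
    X, y = _clusters(rng, {"a": 10, "b": 30}, [(0, 0), (5, 5)])
    out1 = smote(X, y, seed=9)
    out2 = smote(X, y, seed=9)
    assert np.array_equal(out1[0], out2[0])


def test_smote_class_too_small(rng):
    X, y = _clusters(rng, {"tiny": 3, "big": 20}, [(0, 0), (5, 5)])
    with pytest.raises(ValueError, match="tiny"):
        smote(X, y, k_neighbors=5, seed=0)


# --- SVM -------------------------------------------------------------------


def test_svm_separable_training_accuracy(rng):
    X, y = _clusters(rng, {"a": 20, "b": 20}, [(0, 0), (50, 50)])
    clf = train_svm_rbf(X, y)
    assert np.mean(clf.predict(X) == y) == 1.0


def test_svm_memorizing_regime(rng):
    """Large C and a narrow kernel memorize the training set."""
    X = rng.normal(size=(40, 3))
    y = np.array(["p", "q"] * 20)
    clf = train_svm_rbf(X, y, C=1e6, gamma=50.0)
    assert np.mean(clf.predict(X) == y) == 1.0


def test_svm_deterministic(rng):
    X, y = _clusters(rng, {"a": 15, "b": 15, "c": 15}, [(0, 0), (3, 0), (0, 3)])
    p1 = train_svm_rbf(X, y).predict(X)
    p2 = train_svm_rbf(X, y).predict(X)
    assert np.array_equal(p1, p2)


def test_svm_single_class_rejected():
    with pytest.raises(ValueError):
        train_svm_rbf(np.ones((5, 2)), np.array(["a"] * 5))


# --- metrics ---------------------------------------------------------------


def test_metrics_perfect():
    assert compute_metrics(np.diag([5, 5, 5]).astype(int)) == (1.0, 1.0, 1.0)


def test_metrics_hand_example():
    cm = np.array([[8, 2, 0], [1, 7, 2], [0, 1, 9]])
    acc, sens, spec = compute_metrics(cm)
    assert np.isclose(acc, 24 / 30)
    # per-class recalls: 8/10, 7/10, 9/10
    assert np.isclose(sens, np.mean([0.8, 0.7, 0.9]))
    # per-class TN/(TN+FP): 19/20, 17/20, 18/20
    assert np.isclose(spec, np.mean([19 / 20, 17 / 20, 18 / 20]))


def test_metrics_uniform_is_chance():
    cm = np.full((3, 3), 4, dtype=int)
    acc, _, _ = compute_metrics(cm)
    assert np.isclose(acc, 1 / 3)


def test_metrics_empty_rejected():
    with pytest.raises(ValueError):
        compute_metrics(np.zeros((3, 3), dtype=int))


# --- cross-validation ------------------------------------------------------


def _feature_df(rng, counts, centers, spread=0.3, d=6):
    X, y = [], []
    for (label, n), c in zip(counts.items(), centers):
        X.append(rng.normal(c, spread, size=(n, d)))
        y.extend([label] * n)
    df = pd.DataFrame(np.vstack(X), columns=[f"bin_{i+1}" for i in range(d)])
    df["group"] = y
    return df


def test_cv_separable_high_accuracy(rng):
    df = _feature_df(
        rng,
        {"dementia": 12, "mci": 30, "healthy": 60},
        [np.zeros(6), np.full(6, 3.0), np.full(6, -3.0)],
    )
    rep = cross_validate(df, folds=10, seed=0, select=False)
    assert rep.test_accuracy >= 0.9
    assert rep.pooled_test_cm.sum() == len(df)


def test_cv_null_near_chance(rng):
    df = _feature_df(
        rng,
        {"dementia": 12, "mci": 30, "healthy": 60},
        [np.zeros(6)] * 3,
        spread=1.0,
    )
    rep = cross_validate(df, folds=10, seed=1, select=False)
    assert abs(rep.test_accuracy - 1 / 3) < 0.2


def test_cv_determinism(rng):
    df = _feature_df(
        rng, {"a": 15, "b": 20, "c": 25}, [np.zeros(6), np.ones(6), -np.ones(6)]
    )
    r1 = cross_validate(df, folds=5, seed=3, select=False)
    r2 = cross_validate(df, folds=5, seed=3, select=False)
    assert np.array_equal(r1.fold_assignments, r2.fold_assignments)
    assert r1.to_json() == r2.to_json()


def test_cv_global_mode_optimistic(rng):
    """Selecting and oversampling before the split inflates training fit."""
    df = _feature_df(
        rng,
        {"dementia": 12, "mci": 30, "healthy": 60},
        [np.zeros(6), np.full(6, 0.4), np.full(6, -0.4)],
        spread=1.0,
    )
    safe = cross_validate(df, folds=5, seed=4, leakage_mode="safe", select=False)
    glob = cross_validate(df, folds=5, seed=4, leakage_mode="global", select=False)
    assert glob.test_accuracy >= safe.test_accuracy - 0.05


def test_cv_too_many_folds(rng):
    df = _feature_df(rng, {"a": 3, "b": 3}, [np.zeros(6), np.ones(6)])
    with pytest.raises(ValueError):
        cross_validate(df, folds=10, select=False)
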