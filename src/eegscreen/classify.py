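"""Class balancing, SVM training and cross-validated evaluation.

The cohort is imbalanced (10 dementia / 33 MCI / 77 control), so minority
classes are oversampled to the majority count with SMOTE before training an
RBF-kernel support vector machine on the selected spectral features.
Performance is estimated with stratified tenfold cross-validation; accuracy
is the pooled trace fraction, and sensitivity / specificity are one-vs-rest
rates macro-averaged over the three classes.

Two evaluation protocols are exposed.  In ``safe`` mode (the scientific
default) feature selection and SMOTE are fit inside each training fold only,
so no information from held-out subjects leaks into training.  In ``global``
mode both are applied to the full dataset before splitting; this inflates
the apparent performance and is provided to reproduce analyses that balance
and select before cross-validating.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .group_stats import select_features

__all__ = [
    "smote",
    "train_svm_rbf",
    "compute_metrics",
    "cross_validate",
    "ClassificationReport",
]


def smote(
    X: np.ndarray,
    y: Sequence,
    k_neighbors: int = 5,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Synthetic Minority Over-sampling: equalize all class counts.

    Every minority class is grown to the majority-class count; each
    synthetic sample lies on the segment between a randomly chosen minority
    sample and one of its ``k_neighbors`` nearest same-class neighbours,
    with interpolation factor uniform in [0, 1].  Original rows are
    returned first (unchanged), synthetic rows appended; deterministic
    given the seed.  Already-balanced input is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    if np.all(counts == majority):
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    new_X = [X]
    new_y = [y]
    for cls, count in zip(classes, counts):
        deficit = majority - count
        if deficit == 0:
            continue
        if count < k_neighbors + 1:
            raise ValueError(
                f"class {cls!r} has {count} members; SMOTE with "
                f"k_neighbors={k_neighbors} needs at least {k_neighbors + 1}"
            )
        Xc = X[y == cls]
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xc)
        neighbor_idx = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        base = rng.integers(0, count, size=deficit)
        pick = rng.integers(0, k_neighbors, size=deficit)
        gamma = rng.uniform(0.0, 1.0, size=deficit)
        anchors = Xc[base]
        partners = Xc[neighbor_idx[base, pick]]
        synth = anchors + gamma[:, None] * (partners - anchors)
        new_X.append(synth)
        new_y.append(np.full(deficit, cls, dtype=y.dtype))
    return np.concatenate(new_X, axis=0), np.concatenate(new_y, axis=0)


def train_svm_rbf(
    X: np.ndarray,
    y: Sequence,
    C: float = 1.0,
    gamma: str | float = "scale",
) -> SVC:
    """Fit an RBF-kernel SVM (one-vs-one multiclass voting).

    ``gamma='scale'`` sets the kernel width to 1 / (d * Var(X)), a robust
    default when hyperparameters are not tuned.  Deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes to train a classifier")
    clf = SVC(C=C, gamma=gamma, kernel="rbf")
    clf.fit(X, y)
    return clf


def confusion(y_true: Sequence, y_pred: Sequence, classes: Sequence) -> np.ndarray:
    """Confusion matrix with fixed class order (rows true, cols predicted)."""
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def compute_metrics(cm: np.ndarray) -> Tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from a confusion matrix.

    Accuracy is trace / total.  Sensitivity is the macro mean over classes
    of TP / (TP + FN); specificity the macro mean of TN / (TN + FP), in the
    one-vs-rest sense.  Classes absent from the truth rows are excluded
    from both macro means.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0) or not np.issubdtype(cm.dtype, np.integer):
        raise ValueError("confusion matrix must hold non-negative integers")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(cm) / total)
    sens, spec = [], []
    for i in range(cm.shape[0]):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:  # class absent from truth
            continue
        sens.append(tp / (tp + fn))
        spec.append(tn / (tn + fp) if tn + fp > 0 else 1.0)
    return accuracy, float(np.mean(sens)), float(np.mean(spec))


@dataclass
class ClassificationReport:
    """Per-fold confusion matrices and pooled metrics, train and test."""

    classes: List[str]
    fold_train_cm: List[np.ndarray]
    fold_test_cm: List[np.ndarray]
    fold_assignments: np.ndarray
    train_accuracy: float
    train_sensitivity: float
    train_specificity: float
    test_accuracy: float
    test_sensitivity: float
    test_specificity: float
    selected_per_fold: List[List[str]]
    config: Dict = field(default_factory=dict)

    @property
    def pooled_test_cm(self) -> np.ndarray:
        return np.sum(self.fold_test_cm, axis=0)

    @property
    def pooled_train_cm(self) -> np.ndarray:
        return np.sum(self.fold_train_cm, axis=0)

    def to_dict(self) -> Dict:
        return {
            "classes": list(self.classes),
            "fold_train_cm": [cm.tolist() for cm in self.fold_train_cm],
            "fold_test_cm": [cm.tolist() for cm in self.fold_test_cm],
            "fold_assignments": self.fold_assignments.tolist(),
            "train": {
                "accuracy": self.train_accuracy,
                "sensitivity": self.train_sensitivity,
                "specificity": self.train_specificity,
            },
            "test": {
                "accuracy": self.test_accuracy,
                "sensitivity": self.test_sensitivity,
                "specificity": self.test_specificity,
            },
            "selected_per_fold": self.selected_per_fold,
            "config": self.config,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "split": ["train", "test"],
                "accuracy": [self.train_accuracy, self.test_accuracy],
                "sensitivity": [self.train_sensitivity, self.test_sensitivity],
                "specificity": [self.train_specificity, self.test_specificity],
            }
        )


def _standardize(train: np.ndarray, *others: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return tuple((arr - mu) / sd for arr in (train, *others))


def cross_validate(
    table: pd.DataFrame,
    labels: Optional[Sequence] = None,
    folds: int = 10,
    seed: int = 0,
    leakage_mode: str = "safe",
    alpha: float = 0.05,
    p_adjust_method: str = "bonferroni",
    smote_k_neighbors: int = 5,
    C: float = 1.0,
    gamma: str | float = "scale",
    feature_columns: Optional[List[str]] = None,
    select: bool = True,
) -> ClassificationReport:
    """Stratified k-fold evaluation of the select->balance->SVM pipeline.

    ``table`` holds one row per subject with feature columns and a
    ``group`` column (unless ``labels`` is given).  In safe mode the
    Kruskal-Wallis selection and SMOTE are re-fit inside every training
    fold; if a fold selects no feature, all candidates are used for that
    fold.  In global mode selection and SMOTE run once on the full dataset
    (synthetic samples then participate in the folds).  Features are
    standardized with training-fold statistics in both modes.
    """
    from .features import FEATURE_COLUMNS

    if leakage_mode not in ("safe", "global"):
        raise ValueError(f"unknown leakage_mode {leakage_mode!r}")
    cols = feature_columns or [c for c in FEATURE_COLUMNS if c in table.columns]
    y_all = np.asarray(labels if labels is not None else table["group"])
    X_all = table[cols].to_numpy(dtype=float)
    n = X_all.shape[0]
    if folds > n:
        raise ValueError(f"folds={folds} exceeds number of samples {n}")
    classes = sorted(np.unique(y_all).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes")

    global_selected: Optional[List[str]] = None
    if leakage_mode == "global":
        if select:
            sel, _ = select_features(
                table, labels=y_all, alpha=alpha, method=p_adjust_method,
                feature_columns=cols,
            )
            global_selected = sel if sel else list(cols)
        else:
            global_selected = list(cols)
        sub = [cols.index(c) for c in global_selected]
        X_all, y_all = smote(
            X_all[:, sub], y_all, k_neighbors=smote_k_neighbors, seed=seed
        )
        cols_used = global_selected
        table_for_folds = pd.DataFrame(X_all, columns=cols_used)
        table_for_folds["group"] = y_all
    else:
        cols_used = cols
        table_for_folds = None

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    assignments = np.full(y_all.shape[0], -1, dtype=int)
    fold_train_cm: List[np.ndarray] = []
    fold_test_cm: List[np.ndarray] = []
    selected_per_fold: List[List[str]] = []

    for fold, (tr, te) in enumerate(skf.split(X_all, y_all)):
        assignments[te] = fold
        y_tr, y_te = y_all[tr], y_all[te]
        if leakage_mode == "safe" and select:
            fold_table = table.iloc[tr]
            sel, _ = select_features(
                fold_table, labels=y_tr, alpha=alpha, method=p_adjust_method,
                feature_columns=cols,
            )
            use = sel if sel else list(cols)
        else:
            use = list(cols_used)
        idx = [cols_used.index(c) for c in use] if leakage_mode == "global" else [
            cols.index(c) for c in use
        ]
        X_tr, X_te = X_all[tr][:, idx], X_all[te][:, idx]
        if leakage_mode == "safe":
            X_tr, y_tr2 = smote(
                X_tr, y_tr, k_neighbors=smote_k_neighbors, seed=seed + fold
            )
        else:
            y_tr2 = y_tr
        X_tr_s, X_te_s = _standardize(X_tr, X_te)
        clf = train_svm_rbf(X_tr_s, y_tr2, C=C, gamma=gamma)
        fold_train_cm.append(confusion(y_tr2, clf.predict(X_tr_s), classes))
        fold_test_cm.append(confusion(y_te, clf.predict(X_te_s), classes))
        selected_per_fold.append(use)

    pooled_test = np.sum(fold_test_cm, axis=0)
    pooled_train = np.sum(fold_train_cm, axis=0)
    acc_te, sen_te, spe_te = compute_metrics(pooled_test)
    acc_tr, sen_tr, spe_tr = compute_metrics(pooled_train)
    return ClassificationReport(
        classes=classes,
        fold_train_cm=fold_train_cm,
        fold_test_cm=fold_test_cm,
        fold_assignments=assignments,
        train_accuracy=acc_tr,
        train_sensitivity=sen_tr,
        train_specificity=spe_tr,
        test_accuracy=acc_te,
        test_sensitivity=sen_te,
        test_specificity=spe_te,
        selected_per_fold=selected_per_fold,
        config={
            "folds": folds,
            "seed": seed,
            "leakage_mode": leakage_mode,
            "alpha": alpha,
            "p_adjust_method": p_adjust_method,
            "smote_k_neighbors": smote_k_neighbors,
            "C": C,
            "gamma": gamma if isinstance(gamma, str) else float(gamma),
        },
    )
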