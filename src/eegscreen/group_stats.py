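"""Group-difference testing and feature selection.

Each candidate feature (45 one-Hz bins plus 10 band powers) is tested for a
three-group difference with the Kruskal-Wallis rank test; p-values are
corrected for multiplicity over the whole candidate family (Bonferroni by
default, Benjamini-Hochberg FDR available) and features significant at the
5% level become the classifier's predictors.  Pairwise rank-sum post-hoc
comparisons among the three groups are reported for interpretation but do
not drive selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_COLUMNS

__all__ = [
    "FeatureTestResult",
    "kruskal_wallis",
    "adjust_pvalues",
    "select_features",
    "pairwise_posthoc",
]


@dataclass(frozen=True)
class FeatureTestResult:
    feature: str
    H: float
    p: float
    p_adjusted: float
    selected: bool


def kruskal_wallis(*groups: Sequence[float]) -> Tuple[float, float]:
    """Kruskal-Wallis H and its chi-square p-value (k-1 df).

    H is computed from joint ranks with tie correction.  The fully tied
    case (all observations identical) is defined as H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = sps.kruskal(*arrays)
    return float(H), float(p)


def adjust_pvalues(pvalues: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Multiplicity-adjusted p-values.

    ``bonferroni``: min(1, m*p).  ``bh_fdr``: Benjamini-Hochberg step-up
    adjusted values.  Both are order-preserving and never smaller than the
    raw p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        sm_method = "bonferroni"
    elif method == "bh_fdr":
        sm_method = "fdr_bh"
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=sm_method)[1]


def select_features(
    table: pd.DataFrame,
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    method: str = "bonferroni",
    feature_columns: Optional[List[str]] = None,
) -> Tuple[List[str], List[FeatureTestResult]]:
    """Kruskal-Wallis screen over all candidate features.

    ``table`` holds one row per subject; group labels come from ``labels``
    or the table's ``group`` column.  Returns the names of features whose
    adjusted p-value falls below ``alpha`` and the full per-feature test
    results (deterministic).
    """
    cols = feature_columns or [c for c in FEATURE_COLUMNS if c in table.columns]
    if not cols:
        raise ValueError("no candidate feature columns present")
    y = np.asarray(labels if labels is not None else table["group"])
    classes = pd.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two groups for selection")
    stats_raw = []
    for col in cols:
        groups = [table.loc[y == cls, col].to_numpy() for cls in classes]
        H, p = kruskal_wallis(*groups)
        stats_raw.append((col, H, p))
    adjusted = adjust_pvalues([p for _, _, p in stats_raw], method=method)
    results = [
        FeatureTestResult(
            feature=col, H=H, p=p, p_adjusted=float(padj), selected=bool(padj < alpha)
        )
        for (col, H, p), padj in zip(stats_raw, adjusted)
    ]
    selected = [r.feature for r in results if r.selected]
    return selected, results


def pairwise_posthoc(
    table: pd.DataFrame,
    feature: str,
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pairwise Mann-Whitney rank-sum tests for one feature, Bonferroni-
    corrected over the group pairs.  Reported for interpretation only."""
    y = np.asarray(labels if labels is not None else table["group"])
    classes = list(pd.unique(y))
    rows = []
    pairs = [
        (classes[i], classes[j])
        for i in range(len(classes))
        for j in range(i + 1, len(classes))
    ]
    raw = []
    for a, b in pairs:
        xa = table.loc[y == a, feature].to_numpy()
        xb = table.loc[y == b, feature].to_numpy()
        stat, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        raw.append(p)
        rows.append({"feature": feature, "group_a": a, "group_b": b, "U": stat, "p": p})
    adj = adjust_pvalues(raw, method="bonferroni")
    df = pd.DataFrame(rows)
    df["p_adjusted"] = adj
    return df


def results_frame(results: Sequence[FeatureTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "H": r.H,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
                "selected": r.selected,
            }
            for r in results
        ]
    )
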