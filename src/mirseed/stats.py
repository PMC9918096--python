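"""Group comparisons, ROC analysis with optimal cutpoints, fold changes and
Spearman correlations.

Nonparametric tests delegate to scipy; the ROC AUC is the pooled-rank
Mann-Whitney statistic U/(n1*n2) (ties contribute 1/2), its p-value is the
two-sided Mann-Whitney p, and the optimal cutpoint maximizes sensitivity +
specificity over the observed values (Youden's rule), classifying positive
when value >= cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .qc import round_half_up

__all__ = [
    "GroupTestResult",
    "RocResult",
    "kruskal_wallis",
    "mann_whitney",
    "fold_change",
    "roc_curve",
    "optimal_cutpoint",
    "spearman",
]


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    groups: tuple
    n: tuple


@dataclass
class RocResult:
    auc: float
    p_value: float
    cutoff: float
    sensitivity: float
    specificity: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def kruskal_wallis(values, groups) -> GroupTestResult:
    """Kruskal-Wallis H test across >= 3 groups (tie-corrected, chi-square p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = pd.unique(groups)
    if len(names) < 3:
        raise ValueError("kruskal_wallis needs >= 3 groups; "
                         "use mann_whitney for two")
    arrays = [values[groups == g] for g in names]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    h, p = sps.kruskal(*arrays)
    return GroupTestResult(statistic=float(h), p_value=float(p),
                           groups=tuple(names), n=tuple(len(a) for a in arrays))


def mann_whitney(a, b, exact_below: int = 20) -> GroupTestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both samples have n < *exact_below* and the data
    are tie-free; otherwise the normal approximation with tie correction.
    The returned statistic is U for the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) < exact_below and len(b) < exact_below
                         and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupTestResult(statistic=float(res.statistic),
                           p_value=float(min(res.pvalue, 1.0)),
                           groups=("a", "b"), n=(len(a), len(b)))


def fold_change(a, b, percent: bool = False):
    """Ratio of group means, rounded half-up to one decimal.

    *a* and *b* may be value arrays or precomputed means. In percent mode
    returns round(100 * ratio) as an integer.
    """
    mean_a = float(np.mean(a))
    mean_b = float(np.mean(b))
    if mean_b == 0:
        raise ZeroDivisionError("fold change undefined: zero denominator")
    ratio = mean_a / mean_b
    if percent:
        return int(round_half_up(100.0 * ratio))
    return round_half_up(ratio, 1)


def _check_two_classes(labels: np.ndarray):
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")


def optimal_cutpoint(values, labels) -> tuple:
    """Cutoff maximizing sensitivity + specificity (positive iff value >= cutoff).

    All observed values are evaluated as candidate thresholds; ties in the
    criterion are broken toward higher specificity, then lower cutoff.
    Returns (cutoff, sensitivity, specificity).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    pos = values[labels == 1]
    neg = values[labels == 0]
    best = None
    for c in np.unique(values):
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        key = (sens + spec, spec, -c)
        if best is None or key > best[0]:
            best = (key, (float(c), sens, spec))
    return best[1]


def roc_curve(values, labels) -> RocResult:
    """ROC analysis of one marker against a binary outcome.

    Orientation: higher value = positive class; the AUC is not flipped when
    below 0.5. AUC equals the Mann-Whitney U of the positive class over
    n1*n2; significance is the two-sided Mann-Whitney p.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    auc = float(roc_auc_score(labels, values))
    mw = mann_whitney(values[labels == 1], values[labels == 0])
    fpr, tpr, thr = _sk_roc_curve(labels, values)
    cutoff, sens, spec = optimal_cutpoint(values, labels)
    return RocResult(auc=auc, p_value=mw.p_value, cutoff=cutoff,
                     sensitivity=sens, specificity=spec,
                     fpr=fpr, tpr=tpr, thresholds=thr)


def spearman(x, y, min_n: int = 5) -> tuple:
    """Spearman rank correlation (average ranks for ties, t-approximation p).

    Pairs with a missing member are dropped. Returns (rho, p); a constant
    vector yields (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < min_n:
        raise ValueError(f"spearman needs >= {min_n} complete pairs, got {len(x)}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input; Spearman correlation undefined")
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
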