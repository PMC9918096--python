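"""Sample QC, CPM normalization, detection sets, prevalence filter, PCA.

Count matrices are pandas DataFrames with miRNA ids as the index and sample
ids as columns; metadata tables are indexed by sample id.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "cpm_normalize",
    "hemolysis_qc",
    "detection_sets",
    "prevalence_filter",
    "pca_summary",
    "HemolysisQcResult",
    "DetectionSets",
    "PcaSummary",
    "round_half_up",
]

HEMOLYSIS_A414_THRESHOLD = 0.25  # absorbance units; >= threshold is hemolyzed


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (reporting convention for summaries)."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization.

    CPM_ij = count_ij / total_j * 1e6, where total_j is the sample's total
    read count. Raises on samples with zero total (the quantity is
    undefined), naming them.
    """
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    totals = values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = list(counts.columns[zero])
        raise ValueError(f"zero-total sample(s), CPM undefined: {bad}")
    return counts / totals * 1.0e6


@dataclass
class HemolysisQcResult:
    """Per-sample qualification flags plus attrition summary."""

    qualified: pd.Series        # boolean per evaluable sample
    unevaluable: list           # sample ids lacking A414
    n_total: int
    n_qualified: int
    pct_qualified: int          # rounded half-up to integer

    def summary(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_qualified": self.n_qualified,
            "pct_qualified": self.pct_qualified,
            "n_unevaluable": len(self.unevaluable),
        }


def hemolysis_qc(
    meta: pd.DataFrame,
    threshold: float = HEMOLYSIS_A414_THRESHOLD,
    exclude_unevaluable_from_denominator: bool = False,
) -> HemolysisQcResult:
    """Hemolysis / plasma-volume sample QC.

    A sample qualifies iff its A414 absorbance is strictly below *threshold*
    (A414 >= threshold means hemolyzed) and its plasma volume was
    sufficient. Samples missing A414 are flagged unevaluable; they count in
    the denominator unless *exclude_unevaluable_from_denominator*.
    """
    a414 = pd.to_numeric(meta["a414"], errors="coerce")
    vol_ok = meta.get("plasma_volume_ok", pd.Series(True, index=meta.index))
    vol_ok = vol_ok.fillna(True).astype(bool)
    evaluable = a414.notna()
    unevaluable = list(meta.index[~evaluable])
    qualified = (a414 < threshold) & vol_ok & evaluable
    n_total = int(evaluable.sum()) if exclude_unevaluable_from_denominator \
        else len(meta)
    n_q = int(qualified.sum())
    pct = int(round_half_up(100.0 * n_q / n_total)) if n_total else 0
    return HemolysisQcResult(
        qualified=qualified[evaluable],
        unevaluable=unevaluable,
        n_total=n_total,
        n_qualified=n_q,
        pct_qualified=pct,
    )


@dataclass
class DetectionSets:
    """Per-group detected-miRNA sets with all intersection region sizes."""

    group_sets: dict            # group -> set of miRNA ids
    intersections: dict         # frozenset of groups -> set of miRNA ids

    def sizes(self) -> dict:
        out = {g: len(s) for g, s in self.group_sets.items()}
        for key, s in self.intersections.items():
            out["&".join(sorted(key))] = len(s)
        return out

    def exclusive(self, group: str) -> set:
        """miRNAs detected in *group* and in no other group."""
        others = set().union(*(s for g, s in self.group_sets.items()
                               if g != group)) if len(self.group_sets) > 1 else set()
        return self.group_sets[group] - others

    def union(self) -> set:
        return set().union(*self.group_sets.values()) if self.group_sets else set()


def detection_sets(counts: pd.DataFrame, groups: pd.Series | dict) -> DetectionSets:
    """Detected-miRNA sets per group and their pairwise/3-way intersections.

    Detection rule: raw count >= 1 in at least one sample of the group.
    """
    groups = pd.Series(groups)
    group_sets = {}
    for g in groups.unique():
        samples = groups.index[groups == g]
        samples = [s for s in samples if s in counts.columns]
        if not samples:
            warnings.warn(f"group {g!r} has no samples in the count matrix")
            group_sets[g] = set()
            continue
        detected = (counts[samples] >= 1).any(axis=1)
        group_sets[g] = set(counts.index[detected])
    inter = {}
    names = list(group_sets)
    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            inter[frozenset(combo)] = set.intersection(
                *(group_sets[g] for g in combo))
    return DetectionSets(group_sets=group_sets, intersections=inter)


def prevalence_filter(
    counts: pd.DataFrame,
    min_count: int = 1,
    min_fraction: float = 0.8,
) -> pd.DataFrame:
    """Keep miRNAs with count >= min_count in >= ceil(min_fraction * n) samples.

    The default (>=1 read in >=80% of samples) is the read-prevalence filter
    applied before the machine-learning discovery analysis.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0, 1]")
    n = counts.shape[1]
    need = math.ceil(min_fraction * n)
    keep = (counts >= min_count).sum(axis=1) >= need
    return counts.loc[keep]


@dataclass
class PcaSummary:
    scores: pd.DataFrame        # samples x components
    pct_variance: np.ndarray    # percent variance explained per component


def pca_summary(
    cpm: pd.DataFrame,
    n_components: int | None = None,
    log_transform: bool = True,
) -> PcaSummary:
    """PCA of a CPM matrix over samples.

    Operates on log2(CPM + 1) by default, with per-miRNA centering (the
    samples are the observations). Percent variance explained is
    non-increasing and sums to <= 100. Constant input yields all-zero
    scores and variance.
    """
    if cpm.shape[1] < 2:
        raise ValueError("PCA requires >= 2 samples")
    x = cpm.to_numpy(dtype=float).T          # samples x miRNAs
    if log_transform:
        x = np.log2(x + 1.0)
    x = x - x.mean(axis=0, keepdims=True)
    if np.allclose(x, 0):
        k = n_components or min(x.shape)
        scores = pd.DataFrame(np.zeros((x.shape[0], k)), index=cpm.columns,
                              columns=[f"PC{i+1}" for i in range(k)])
        return PcaSummary(scores=scores, pct_variance=np.zeros(k))
    k = n_components or min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    return PcaSummary(
        scores=pd.DataFrame(scores, index=cpm.columns,
                            columns=[f"PC{i+1}" for i in range(scores.shape[1])]),
        pct_variance=pca.explained_variance_ratio_ * 100.0,
    )
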