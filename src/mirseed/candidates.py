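"""Candidate-miRNA selection rules for validation shortlists.

Applies the study's filter rules to a differential-expression table:
upregulated candidates need log2FC >= 1.0, adjusted p below the FDR cut,
mean CPM >= 30 in the injury (contrast) group, and brain enrichment;
downregulated candidates need log2FC <= -1.0 and mean CPM >= 100 in *both*
groups. Thresholds are inclusive, since boundary cases (e.g. CPM 31 under
"CPM >= 30") are admitted. Manual additions (candidates quantifiable by PCR
but absent from sequencing) enter through an allow-list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CandidateList", "select_upregulated", "select_downregulated"]

PADJ_MAX = 0.05          # "low p-value" operationalized as the DE FDR rule
LOG2FC_MIN_UP = 1.0
CPM_MIN_UP = 30.0
LOG2FC_MAX_DOWN = -1.0
CPM_MIN_DOWN = 100.0


@dataclass
class CandidateList:
    """Shortlist of candidate biomarkers in one direction."""

    direction: str                       # "up" or "down"
    entries: pd.DataFrame                # mirna_id index: log2fc, padj, cpm columns
    manual_additions: list = field(default_factory=list)
    missing_annotation: list = field(default_factory=list)

    @property
    def mirna_ids(self) -> list:
        return list(self.entries.index) + list(self.manual_additions)


def _group_mean_cpm(cpm: pd.DataFrame, groups: pd.Series, group: str) -> pd.Series:
    samples = [s for s in cpm.columns if groups.get(s) == group]
    if not samples:
        raise ValueError(f"group {group!r} has no samples in the CPM matrix")
    return cpm[samples].mean(axis=1)


def select_upregulated(
    de: pd.DataFrame,
    cpm: pd.DataFrame,
    groups: pd.Series | dict,
    contrast_group: str = "TBI",
    annotation: pd.DataFrame | None = None,
    log2fc_min: float = LOG2FC_MIN_UP,
    cpm_min: float = CPM_MIN_UP,
    padj_max: float = PADJ_MAX,
    require_brain: bool = True,
    allow_list: tuple = (),
) -> CandidateList:
    """Upregulated candidates: log2FC >= log2fc_min, padj <= padj_max,
    mean CPM >= cpm_min in the contrast (injury) group, brain-enriched.

    *annotation* is a table indexed by miRNA id with a boolean
    ``brain_enriched`` column; when *require_brain* is set, passing miRNAs
    without an annotation row are excluded with a warning, otherwise kept
    and flagged. Returned entries are sorted by adjusted p ascending.
    """
    groups = pd.Series(groups)
    mean_cpm = _group_mean_cpm(cpm, groups, contrast_group)
    tab = de.join(mean_cpm.rename("group_cpm"), how="inner")
    keep = (
        (tab["log2FoldChange"] >= log2fc_min)
        & (tab["padj"] <= padj_max)
        & (tab["group_cpm"] >= cpm_min)
    )
    keep = keep.fillna(False)
    missing = []
    if annotation is not None or require_brain:
        ann = annotation if annotation is not None else pd.DataFrame(
            columns=["brain_enriched"])
        enriched = ann.get("brain_enriched", pd.Series(dtype=bool))
        for mid in tab.index[keep]:
            if mid not in enriched.index:
                missing.append(mid)
                if require_brain:
                    warnings.warn(f"{mid} passes filters but lacks a "
                                  "brain-enrichment annotation; excluded")
                    keep.loc[mid] = False
            elif require_brain and not bool(enriched.loc[mid]):
                keep.loc[mid] = False
    entries = tab.loc[keep, ["log2FoldChange", "padj", "group_cpm"]]
    entries = entries.sort_values("padj")
    return CandidateList(direction="up", entries=entries,
                         manual_additions=list(allow_list),
                         missing_annotation=missing)


def select_downregulated(
    de: pd.DataFrame,
    cpm: pd.DataFrame,
    groups: pd.Series | dict,
    contrast: tuple = ("TBI", "sham"),
    log2fc_max: float = LOG2FC_MAX_DOWN,
    cpm_min: float = CPM_MIN_DOWN,
    padj_max: float = PADJ_MAX,
) -> CandidateList:
    """Downregulated candidates: log2FC <= log2fc_max, padj <= padj_max,
    mean CPM >= cpm_min in *both* contrast groups."""
    groups = pd.Series(groups)
    cpm_a = _group_mean_cpm(cpm, groups, contrast[0])
    cpm_b = _group_mean_cpm(cpm, groups, contrast[1])
    tab = de.join(cpm_a.rename("group_cpm"), how="inner").join(
        cpm_b.rename("other_group_cpm"), how="inner")
    keep = (
        (tab["log2FoldChange"] <= log2fc_max)
        & (tab["padj"] <= padj_max)
        & (tab["group_cpm"] >= cpm_min)
        & (tab["other_group_cpm"] >= cpm_min)
    ).fillna(False)
    entries = tab.loc[keep, ["log2FoldChange", "padj", "group_cpm",
                             "other_group_cpm"]].sort_values("padj")
    return CandidateList(direction="down", entries=entries)
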