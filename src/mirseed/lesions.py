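"""Quantitative-T2 lesion volumetry and biomarker/lesion correlation.

Cortical voxels are classified as normal when their T2 falls inside the
band defined by the 2.5th and 97.5th percentiles of all masked voxels of
all control (sham-operated) volumes pooled across timepoints (~45-55 ms for
healthy rat cortex); voxels outside the band are abnormal and count toward
lesion volume (abnormal voxels x voxel size). Band endpoints are classified
normal (the band is inclusive). Percentiles use linear interpolation
between order statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import spearman
from .synthetic import T2Volume

__all__ = ["LesionBand", "LesionMeasurement", "normal_t2_band",
           "lesion_volume", "correlate_biomarker_lesion"]


@dataclass(frozen=True)
class LesionBand:
    """Normal-T2 range in ms; values outside [lower, upper] are abnormal."""

    lower_ms: float
    upper_ms: float
    degenerate: bool = False

    def __post_init__(self):
        if self.lower_ms > self.upper_ms:
            raise ValueError("lower_ms must be <= upper_ms")


@dataclass
class LesionMeasurement:
    volume_mm3: float
    n_abnormal: int
    n_below: int        # hemorrhage-like (short T2)
    n_above: int        # edema-like (long T2)
    n_masked: int


def normal_t2_band(
    control_volumes: list,
    lower_pct: float = 2.5,
    upper_pct: float = 97.5,
) -> LesionBand:
    """Normal T2 band from pooled masked voxels of all control volumes.

    The lower/upper limits are the 2.5th and 97.5th percentiles over every
    masked voxel of every control volume across all timepoints.
    """
    pools = [v.data[v.mask].ravel() for v in control_volumes]
    pooled = np.concatenate(pools) if pools else np.array([])
    if pooled.size == 0:
        raise ValueError("empty control voxel pool")
    lo, hi = np.percentile(pooled, [lower_pct, upper_pct])
    degenerate = lo == hi
    if degenerate:
        warnings.warn("degenerate band: all control voxels identical")
    return LesionBand(lower_ms=float(lo), upper_ms=float(hi),
                      degenerate=degenerate)


def lesion_volume(volume: T2Volume, band: LesionBand) -> LesionMeasurement:
    """Abnormal-voxel lesion volume under *band*.

    Abnormal iff T2 < lower or T2 > upper (endpoints are normal); volume =
    abnormal count x voxel volume, with short-T2 and long-T2 counts
    reported separately.
    """
    vals = volume.data[volume.mask]
    below = vals < band.lower_ms
    above = vals > band.upper_ms
    n_below = int(below.sum())
    n_above = int(above.sum())
    n_abn = n_below + n_above
    return LesionMeasurement(
        volume_mm3=float(n_abn * volume.voxel_volume_mm3),
        n_abnormal=n_abn, n_below=n_below, n_above=n_above,
        n_masked=int(volume.mask.sum()),
    )


def correlate_biomarker_lesion(
    mirna_levels: pd.DataFrame,
    lesion_metrics: pd.DataFrame,
    min_n: int = 5,
) -> pd.DataFrame:
    """Spearman correlation of per-sample miRNA levels with lesion metrics.

    *mirna_levels*: samples x miRNAs; *lesion_metrics*: samples x metrics
    (e.g. T2 lesion volume per imaging timepoint, or a histological lesion
    area). Pairs with a missing member are dropped per miRNA x metric cell;
    rows with fewer than *min_n* pairs are flagged and carry NaN.
    Returns a tidy table (mirna_id, metric, n, rho, p, low_n).
    """
    rows = []
    common = mirna_levels.index.intersection(lesion_metrics.index)
    levels = mirna_levels.loc[common]
    metrics = lesion_metrics.loc[common]
    for mirna in levels.columns:
        for metric in metrics.columns:
            x = levels[mirna].to_numpy(dtype=float)
            y = metrics[metric].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < min_n:
                rows.append((mirna, metric, n, np.nan, np.nan, True))
                continue
            rho, p = spearman(x[ok], y[ok], min_n=min_n)
            rows.append((mirna, metric, n, rho, p, False))
    return pd.DataFrame(rows, columns=["mirna_id", "metric", "n", "rho", "p",
                                       "low_n"])
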