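"""qPCR and ddPCR relative quantification and reference-gene stability.

qPCR expression is normalized to an endogenous reference with 2^-dCt;
ddPCR droplet counts are converted to absolute concentration via the
Poisson partition correction and normalized as target/reference ratios.
Reference choice is supported by a geNorm-style stability ranking (M value
= mean SD of pairwise log2 expression ratios; lower is more stable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "delta_ct_normalize",
    "qpcr_relative_expression",
    "droplet_to_concentration",
    "ddpcr_normalize",
    "ddpcr_expression",
    "genorm_stability",
    "genorm_ranking",
    "plate_drift_check",
]


def delta_ct_normalize(ct_target, ct_reference):
    """Relative expression 2^-(Ct_target - Ct_reference).

    Accepts scalars or arrays; replicate Cts should be averaged on the Ct
    scale before calling (see :func:`qpcr_relative_expression`).
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if np.any(ct_target <= 0) or np.any(ct_reference <= 0):
        raise ValueError("Ct values must be positive")
    out = np.exp2(-(ct_target - ct_reference))
    return float(out) if out.ndim == 0 else out


def qpcr_relative_expression(
    table: pd.DataFrame,
    reference_assay: str,
    sample_col: str = "sample_id",
    assay_col: str = "assay_id",
    ct_col: str = "ct",
) -> pd.DataFrame:
    """Per-sample 2^-dCt expression from a long qPCR Ct table.

    Replicates are averaged on the Ct scale before the transform. Samples
    without a reference Ct are excluded (recorded via a warning). Returns a
    samples x assays matrix of relative expression.
    """
    mean_ct = table.pivot_table(index=sample_col, columns=assay_col,
                                values=ct_col, aggfunc="mean")
    if reference_assay not in mean_ct.columns:
        raise ValueError(f"reference assay {reference_assay!r} absent")
    has_ref = mean_ct[reference_assay].notna()
    dropped = list(mean_ct.index[~has_ref])
    if dropped:
        warnings.warn(f"samples without reference Ct excluded: {dropped}")
    mean_ct = mean_ct[has_ref]
    ref = mean_ct[reference_assay]
    rel = np.exp2(-(mean_ct.sub(ref, axis=0)))
    return rel.drop(columns=[reference_assay])


def droplet_to_concentration(
    positives: int, total: int, droplet_volume: float
) -> float:
    """Poisson partition correction: c = -ln(1 - k/n) / v (copies/uL).

    Zero positives map to 0.0 (below limit of detection); a fully positive
    well is saturated and has no finite estimate.
    """
    if droplet_volume <= 0:
        raise ValueError("droplet_volume must be positive")
    if not 0 <= positives <= total:
        raise ValueError("positives must lie in [0, total]")
    if positives == total:
        raise ValueError("saturated well (all droplets positive); "
                         "concentration not estimable")
    if positives == 0:
        return 0.0
    return float(-np.log1p(-positives / total) / droplet_volume)


def ddpcr_normalize(target_conc: float, reference_conc: float) -> float:
    """Normalized expression = target / reference concentration."""
    if reference_conc <= 0:
        raise ValueError("reference concentration must be positive; "
                         "sample unevaluable")
    return float(target_conc) / float(reference_conc)


def ddpcr_expression(
    table: pd.DataFrame,
    reference_assay: str,
    sample_col: str = "sample_id",
    assay_col: str = "assay_id",
) -> pd.DataFrame:
    """Per-sample normalized ddPCR expression from a long droplet table.

    Expects columns ``positives``, ``total`` and ``droplet_volume_ul`` (or a
    precomputed ``copies_per_ul``). Replicate wells of the same
    sample/assay are merged by *pooling droplet counts* before the Poisson
    correction, which is more stable than averaging per-well concentrations.
    Samples whose reference concentration is zero are flagged unevaluable
    and dropped. Returns a samples x assays matrix.
    """
    if "copies_per_ul" in table.columns and "positives" not in table.columns:
        conc = table.pivot_table(index=sample_col, columns=assay_col,
                                 values="copies_per_ul", aggfunc="mean")
    else:
        pooled = table.groupby([sample_col, assay_col]).agg(
            positives=("positives", "sum"), total=("total", "sum"),
            droplet_volume_ul=("droplet_volume_ul", "first"))
        conc = pooled.apply(
            lambda r: droplet_to_concentration(int(r["positives"]),
                                               int(r["total"]),
                                               r["droplet_volume_ul"]),
            axis=1).unstack(assay_col)
    if reference_assay not in conc.columns:
        raise ValueError(f"reference assay {reference_assay!r} absent")
    ref = conc[reference_assay]
    bad = ref.isna() | (ref <= 0)
    if bad.any():
        warnings.warn("samples with zero/missing reference concentration "
                      f"unevaluable: {list(conc.index[bad])}")
    conc = conc[~bad]
    out = conc.div(conc[reference_assay], axis=0)
    return out.drop(columns=[reference_assay])


@dataclass
class StabilityResult:
    assay_id: str
    m_value: float
    rank: int


def genorm_stability(expr: pd.DataFrame) -> pd.DataFrame:
    """geNorm stability M per assay (rows = assays, columns = samples).

    M_j = mean over k != j of the SD over samples of log2(expr_j / expr_k);
    lower M means a more stable candidate reference. Requires >= 3 assays
    and strictly positive expression.
    """
    if expr.shape[0] < 3:
        raise ValueError("geNorm needs >= 3 candidate assays")
    x = expr.to_numpy(dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("expression values must be positive and finite")
    logx = np.log2(x)
    n = logx.shape[0]
    m = np.zeros(n)
    for j in range(n):
        diffs = logx[j][None, :] - logx    # (n, samples) pairwise log ratios
        sds = diffs.std(axis=1, ddof=1)
        m[j] = np.delete(sds, j).mean()
    out = pd.DataFrame({"m_value": m}, index=expr.index)
    out["rank"] = out["m_value"].rank(method="first").astype(int)
    return out.sort_values("m_value")


def genorm_ranking(expr: pd.DataFrame) -> list:
    """Iterative geNorm exclusion order, least stable first.

    Repeatedly removes the assay with the highest M until two remain; the
    returned list is ordered from least to most stable, with the final,
    indistinguishable pair last (sorted by their M in the last round).
    """
    remaining = expr.copy()
    order = []
    while remaining.shape[0] > 3:
        m = genorm_stability(remaining)
        worst = m.index[-1]
        order.append(worst)
        remaining = remaining.drop(index=worst)
    m = genorm_stability(remaining)
    order.extend(list(m.index[::-1]))
    return order


def plate_drift_check(
    control_values: pd.Series, max_fold: float = 2.0
) -> pd.Series:
    """Flag plates whose control sample deviates > *max_fold* from the grand
    geometric mean of all plate controls. No correction is applied."""
    vals = control_values.astype(float)
    if (vals <= 0).any():
        raise ValueError("control values must be positive")
    grand = np.exp(np.log(vals).mean())
    ratio = np.maximum(vals / grand, grand / vals)
    return ratio > max_fold
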