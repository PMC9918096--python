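"""Simplified negative-binomial differential expression.

A deliberately transparent stand-in for a DESeq2-style analysis: median-of-
ratios size factors, per-miRNA method-of-moments dispersion, and a two-group
NB GLM (log link) Wald test with Benjamini-Hochberg adjustment. It omits
DESeq2's Cox-Reid dispersion shrinkage, independent filtering and LFC
shrinkage; its validity is established by simulation-based error control
rather than numerical agreement with DESeq2.

The per-miRNA GLM is fit by iteratively reweighted least squares, vectorized
across all miRNAs simultaneously (each iteration solves a 2x2 weighted
least-squares system per miRNA in closed form).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["size_factors", "estimate_dispersion", "nb_wald_test"]

DISPERSION_FLOOR = 1e-8
DISPERSION_CAP = 20.0
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
LOG2 = np.log(2.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over miRNAs of count_ij / geometric_mean_i, computed
    over miRNAs with all-positive counts, then normalized to geometric mean
    1. Falls back to total-count scaling (with a warning) when no miRNA has
    positive counts in every sample.
    """
    x = counts.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        sub = x[all_pos]
        geo = np.exp(np.log(sub).mean(axis=1, keepdims=True))
        factors = np.median(sub / geo, axis=0)
    else:
        warnings.warn("no miRNA with positive counts in all samples; "
                      "falling back to total-count size factors")
        totals = x.sum(axis=0)
        if np.any(totals == 0):
            raise ValueError("sample(s) with zero total counts")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series | None = None,
    groups: pd.Series | None = None,
    floor: float = DISPERSION_FLOOR,
    cap: float = DISPERSION_CAP,
) -> pd.Series:
    """Per-miRNA method-of-moments NB dispersion on normalized counts.

    alpha_hat = max(floor, (s^2 - mu_bar) / mu_bar^2) with s^2 the sample
    variance of normalized counts. When *groups* is given the variance is
    pooled within groups (group means removed) so that true between-group
    effects do not inflate the dispersion; each group then needs >= 2
    samples.
    """
    if sf is None:
        sf = size_factors(counts)
    q = counts.to_numpy(dtype=float) / sf.to_numpy(dtype=float)[None, :]
    mu = q.mean(axis=1)
    if groups is not None:
        groups = pd.Series(groups).loc[counts.columns]
        ss = np.zeros(q.shape[0])
        dof = 0
        for g in groups.unique():
            idx = (groups == g).to_numpy()
            if idx.sum() < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
            sub = q[:, idx]
            ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            dof += idx.sum() - 1
        var = ss / dof
    else:
        if q.shape[1] < 2:
            raise ValueError("dispersion estimation requires >= 2 samples")
        var = q.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    alpha = np.clip(alpha, floor, cap)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _irls_two_group(y, offset, group_ind, alpha, tol=IRLS_TOL,
                    max_iter=IRLS_MAX_ITER):
    """Vectorized NB GLM IRLS for the design [intercept, group indicator].

    y: (m, n) counts; offset: (n,) log size factors; group_ind: (n,) 0/1;
    alpha: (m,) dispersions. Returns (beta1, se1, converged), with beta1 the
    natural-log fold change of group 1 over group 0.
    """
    m, n = y.shape
    a_idx = group_ind.astype(bool)
    # init from group means of normalized counts, pseudocounted
    qn = y / np.exp(offset)[None, :]
    mean_b = qn[:, ~a_idx].mean(axis=1) + 0.125
    mean_a = qn[:, a_idx].mean(axis=1) + 0.125
    b0 = np.log(mean_b)
    b1 = np.log(mean_a) - np.log(mean_b)
    converged = np.zeros(m, dtype=bool)
    active = np.ones(m, dtype=bool)
    x1 = group_ind.astype(float)
    for _ in range(max_iter):
        eta = offset[None, :] + b0[:, None] + b1[:, None] * x1[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (b0[:, None] + b1[:, None] * x1[None, :]) + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = w[:, a_idx].sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w[:, a_idx] * z[:, a_idx]).sum(axis=1)
        det = sw * swx - swx**2
        det = np.where(det <= 0, np.nan, det)
        nb0 = (swx * swz - swx * swxz) / det
        nb1 = (sw * swxz - swx * swz) / det
        step = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        b0 = np.where(active & np.isfinite(nb0), nb0, b0)
        b1 = np.where(active & np.isfinite(nb1), nb1, b1)
        newly = active & (step < tol)
        converged |= newly
        active &= ~newly
        if not active.any():
            break
    eta = np.clip(offset[None, :] + b0[:, None] + b1[:, None] * x1[None, :],
                  -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    sw = w.sum(axis=1)
    swx = w[:, a_idx].sum(axis=1)
    det = sw * swx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = sw / det
    se1 = np.sqrt(np.where(var_b1 > 0, var_b1, np.nan))
    return b1, se1, converged


def nb_wald_test(
    counts: pd.DataFrame,
    groups: pd.Series | dict,
    contrast: tuple,
    sf: pd.Series | None = None,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-miRNA NB Wald test for *contrast* = (group_a, group_b).

    Positive log2FoldChange means higher in group_a. miRNAs with zero reads
    in every sample of the contrast are excluded before testing (their row
    carries NaN statistics and is recorded via the ``tested`` column).
    Returns a DESeq2-style table: baseMean, log2FoldChange, lfcSE, stat,
    pvalue, padj.
    """
    group_a, group_b = contrast
    groups = pd.Series(groups)
    samples = [s for s in counts.columns if groups.get(s) in (group_a, group_b)]
    if not samples:
        raise ValueError("contrast selects no samples")
    sub_groups = groups.loc[samples]
    for g in contrast:
        if (sub_groups == g).sum() == 0:
            raise ValueError(f"contrast group {g!r} is empty")
        if (sub_groups == g).sum() < 2:
            raise ValueError(
                f"contrast {group_a} vs {group_b}: group {g!r} has a single sample")
    sub = counts[samples]
    if sf is None:
        sf = size_factors(sub)
    else:
        sf = sf.loc[samples]
    if dispersion is None:
        dispersion = estimate_dispersion(sub, sf, groups=sub_groups)

    nonzero = sub.sum(axis=1) > 0
    y = sub.loc[nonzero].to_numpy(dtype=float)
    alpha = dispersion.loc[nonzero[nonzero].index].to_numpy(dtype=float)
    offset = np.log(sf.to_numpy(dtype=float))
    ind = (sub_groups == group_a).to_numpy().astype(float)

    b1, se1, conv = _irls_two_group(y, offset, ind, alpha)
    log2fc = b1 / LOG2
    se_log2fc = se1 / LOG2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se_log2fc
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    pvals = np.where(conv & np.isfinite(wald), pvals, np.nan)

    base_mean = (y / np.exp(offset)[None, :]).mean(axis=1)
    out = pd.DataFrame(index=counts.index, columns=[
        "baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj"],
        dtype=float)
    out["tested"] = False
    out.loc[nonzero, "baseMean"] = base_mean
    out.loc[nonzero, "log2FoldChange"] = log2fc
    out.loc[nonzero, "lfcSE"] = se_log2fc
    out.loc[nonzero, "stat"] = wald
    out.loc[nonzero, "pvalue"] = pvals
    out.loc[nonzero, "tested"] = True

    tested = out["pvalue"].notna()
    if tested.any():
        out.loc[tested, "padj"] = multipletests(
            out.loc[tested, "pvalue"].to_numpy(), method="fdr_bh")[1]
    return out
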