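"""Multivariate biomarker panel procedures.

Two bespoke procedures built around leave-one-out (LOO) cross-validation:

1. :func:`nested_loocv_logistic` — discovery-stage logistic regression with
   per-fold feature selection (recursive elimination or F-score filter) and
   an inner-CV grid search over regularization level, selection method,
   number of features and L1 vs L2 penalty. Performance is the pooled CV
   AUC over the concatenated out-of-fold predicted probabilities; feature
   importance is the mean |coefficient| over outer folds, normalized to sum
   to one.

2. :func:`glmnet_panel_selection` / :func:`refit_logistic_cv_auc` /
   :func:`bca_bootstrap_ci` — the elastic-net panel pipeline: per outer LOO
   fold a class-weighted elastic-net logistic regression (mixing 0.5 =
   equal LASSO/Ridge weighting) with the penalty chosen by inner CV on
   binomial deviance; features whose coefficient is zero in the majority of
   outer folds are excluded; the surviving panel is refit unpenalized, its
   pooled LOO CV AUC reported with a 95% bias-corrected and accelerated
   (BCa) bootstrap confidence interval (10,000 resamples).

All penalized fits use an internal IRLS + coordinate-descent solver (the
glmnet algorithm) compiled with numba; sklearn's elastic-net logistic
regression serves as an independent cross-check in the test suite.

Standardization, feature selection and penalty choice happen strictly
inside training folds — no statistic of a held-out sample ever enters its
own fold's fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata
import statsmodels.api as sm

from .stats import mann_whitney

__all__ = [
    "PanelConfig",
    "NestedCvResult",
    "PanelResult",
    "default_grid",
    "nested_loocv_logistic",
    "glmnet_panel_selection",
    "refit_logistic_cv_auc",
    "bca_bootstrap_ci",
    "elastic_net_panel",
    "leak_probe_auc",
    "enet_logistic_path",
]

_EPS = 1e-5


# ---------------------------------------------------------------------------
# penalized logistic solver (IRLS + coordinate descent, glmnet algorithm)
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _enet_path_std(Xs, y, w, alpha, lambdas, tol, max_irls, max_cd):
    """Elastic-net logistic path on a pre-standardized design.

    Minimizes (1/n) sum_i w_i * logloss_i + lam * (alpha*|b|_1 +
    (1-alpha)/2*|b|_2^2) with w normalized to mean 1 and an unpenalized
    intercept. Returns (intercepts, coefs) per lambda, warm-started down
    the path, on the standardized scale.
    """
    n, p = Xs.shape
    nl = lambdas.shape[0]
    b0s = np.zeros(nl)
    B = np.zeros((nl, p))
    beta = np.zeros(p)

    sw = 0.0
    swy = 0.0
    for i in range(n):
        sw += w[i]
        swy += w[i] * y[i]
    pbar = swy / sw
    if pbar < _EPS:
        pbar = _EPS
    if pbar > 1.0 - _EPS:
        pbar = 1.0 - _EPS
    b0 = np.log(pbar / (1.0 - pbar))

    eta = np.zeros(n)
    Gc = np.zeros((p, p))
    bc = np.zeros(p)
    Sx = np.zeros(p)

    for li in range(nl):
        lam = lambdas[li]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        for _ in range(max_irls):
            # working response and weights at the current linear predictor
            S = 0.0
            Sz = 0.0
            for j in range(p):
                Sx[j] = 0.0
                bc[j] = 0.0
                for k in range(p):
                    Gc[j, k] = 0.0
            for i in range(n):
                e = b0
                for j in range(p):
                    e += Xs[i, j] * beta[j]
                eta[i] = e
                mu = 1.0 / (1.0 + np.exp(-e))
                if mu < _EPS:
                    mu = _EPS
                if mu > 1.0 - _EPS:
                    mu = 1.0 - _EPS
                om = w[i] * mu * (1.0 - mu) / n
                z = e + (y[i] - mu) / (mu * (1.0 - mu))
                S += om
                Sz += om * z
                for j in range(p):
                    xj = Xs[i, j]
                    oxj = om * xj
                    Sx[j] += oxj
                    bc[j] += oxj * z
                    for k in range(j, p):
                        Gc[j, k] += oxj * Xs[i, k]
            for j in range(p):
                for k in range(j, p):
                    g = Gc[j, k] - Sx[j] * Sx[k] / S
                    Gc[j, k] = g
                    Gc[k, j] = g
                bc[j] = bc[j] - Sx[j] * Sz / S
            # coordinate descent on the centered quadratic subproblem
            max_outer_delta = 0.0
            for _cd in range(max_cd):
                maxd = 0.0
                for j in range(p):
                    g = bc[j]
                    for k in range(p):
                        g -= Gc[j, k] * beta[k]
                    g += Gc[j, j] * beta[j]
                    denom = Gc[j, j] + l2
                    if denom <= 0.0:
                        newb = 0.0
                    elif g > l1:
                        newb = (g - l1) / denom
                    elif g < -l1:
                        newb = (g + l1) / denom
                    else:
                        newb = 0.0
                    d = newb - beta[j]
                    if d != 0.0:
                        ad = abs(d)
                        if ad > maxd:
                            maxd = ad
                        beta[j] = newb
                if maxd > max_outer_delta:
                    max_outer_delta = maxd
                if maxd < tol:
                    break
            xb = 0.0
            for j in range(p):
                xb += Sx[j] * beta[j]
            nb0 = (Sz - xb) / S
            if abs(nb0 - b0) > max_outer_delta:
                max_outer_delta = abs(nb0 - b0)
            b0 = nb0
            if max_outer_delta < tol:
                break
        b0s[li] = b0
        for j in range(p):
            B[li, j] = beta[j]
    return b0s, B


def _standardize(X):
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds_safe = np.where(sds > 0, sds, 1.0)
    return (X - means) / sds_safe, means, sds_safe


def enet_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float = 0.5,
    sample_weight: np.ndarray | None = None,
    tol: float = 1e-7,
    max_irls: int = 50,
    max_cd: int = 200,
):
    """Weighted elastic-net logistic regression over a lambda path.

    Features are standardized internally; returned ``(intercepts, coefs)``
    are on the original scale, one row per lambda (decreasing lambdas give
    warm starts). ``alpha`` is the L1 mixing fraction (1 = LASSO,
    0 = Ridge, 0.5 = equal weighting).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    n = len(y)
    if sample_weight is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weight, dtype=np.float64)
        w = w / w.mean()
    Xs, means, sds = _standardize(X)
    b0s, B = _enet_path_std(np.ascontiguousarray(Xs), y, w, float(alpha),
                            lambdas, tol, max_irls, max_cd)
    coefs = B / sds
    intercepts = b0s - coefs @ means
    return intercepts, coefs


def _lambda_path(Xs, y, w, alpha, n_lambda, min_ratio):
    """glmnet-style lambda path from lambda_max down, log-spaced."""
    n = len(y)
    pbar = np.clip(np.average(y, weights=w), _EPS, 1 - _EPS)
    grad = np.abs(Xs.T @ (w * (y - pbar))) / n
    lam_max = grad.max() / max(alpha, 1e-3)
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _fit_single(X, y, lam, alpha, sample_weight=None):
    """One penalized fit; returns (intercept, coef) on the original scale."""
    icepts, coefs = enet_logistic_path(X, y, np.array([lam]), alpha,
                                       sample_weight)
    return icepts[0], coefs[0]


def _predict_proba(intercept, coef, X):
    eta = np.clip(intercept + X @ coef, -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


def _fast_auc(labels, scores):
    """AUC = Mann-Whitney U / (n1*n0) with average ranks for ties."""
    labels = np.asarray(labels)
    r = rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    u = r[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def _binomial_deviance(y, prob, weight):
    prob = np.clip(prob, _EPS, 1 - _EPS)
    ll = y * np.log(prob) + (1 - y) * np.log(1 - prob)
    return float(-2.0 * np.sum(weight * ll) / np.sum(weight))


def _stratified_folds(y, k, rng):
    """Index arrays of k stratified folds (both classes in every fold when
    class counts allow)."""
    y = np.asarray(y)
    folds = [[] for _ in range(k)]
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(i)
    return [np.array(sorted(f), dtype=int) for f in folds if len(f)]


def _balance_weights(y):
    """Observation weights inversely proportional to class frequency."""
    y = np.asarray(y)
    n = len(y)
    w = np.empty(n, dtype=float)
    for cls in (0, 1):
        m = y == cls
        w[m] = n / (2.0 * max(m.sum(), 1))
    return w


# ---------------------------------------------------------------------------
# nested leave-one-out logistic discovery analysis
# ---------------------------------------------------------------------------

def default_grid(n_features: int) -> dict:
    """Default hyperparameter grid for the nested-LOOCV discovery analysis.

    Regularization levels C log-spaced over six decades, both selection
    methods, L1 and L2 penalties, and every panel size up to n_features.
    """
    return {
        "C": list(np.geomspace(1e-3, 1e2, 6)),
        "penalty": ["l1", "l2"],
        "selector": ["f_score", "rfe"],
        "n_features": list(range(1, n_features + 1)),
    }


@dataclass
class NestedCvResult:
    cv_auc: float
    pooled_predictions: pd.Series      # out-of-fold probability per sample
    fold_coefs: pd.DataFrame           # outer folds x features (0 = unselected)
    fold_configs: list                 # chosen (selector, k, penalty, C) per fold
    feature_importance: pd.Series      # non-negative, sums to 1, descending


def _f_score_ranking(X, y):
    """Features ordered by decreasing two-class ANOVA F."""
    x1 = X[y == 1]
    x0 = X[y == 0]
    n1, n0 = len(x1), len(x0)
    m1, m0 = x1.mean(axis=0), x0.mean(axis=0)
    gm = X.mean(axis=0)
    between = n1 * (m1 - gm) ** 2 + n0 * (m0 - gm) ** 2
    within = ((x1 - m1) ** 2).sum(axis=0) + ((x0 - m0) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = between / np.where(within > 0, within / (n1 + n0 - 2), np.inf)
    f = np.where(np.isfinite(f), f, 0.0)
    return np.argsort(-f, kind="stable")


def _rfe_ranking(X, y, penalty, C, sample_weight=None):
    """Recursive feature elimination order using penalized logistic |coef|.

    Returns features ordered so that the first k entries are the k
    survivors of elimination down to k features.
    """
    n = X.shape[0]
    lam = 1.0 / (C * n)
    alpha = 1.0 if penalty == "l1" else 0.0
    active = list(range(X.shape[1]))
    eliminated = []
    while len(active) > 1:
        _, coef = _fit_single(X[:, active], y, lam, alpha, sample_weight)
        j = int(np.argmin(np.abs(coef)))
        eliminated.append(active.pop(j))
    order = active + eliminated[::-1]
    return np.array(order, dtype=int)


def _outer_fold_fit(X_tr, y_tr, x_te, grid, rng, inner_k=5):
    """Fit one outer fold: inner-CV grid search, final refit, held-out prob.

    Standardization and selection use the training fold only; the held-out
    sample is transformed with training-fold parameters. All fits use
    class-balancing observation weights so that leave-one-out class-ratio
    shifts do not bias the pooled out-of-fold probabilities (without them,
    pooled LOO AUC is systematically pessimistic under class imbalance).
    Returns (probability, coef vector in original feature space, chosen
    config).
    """
    means = X_tr.mean(axis=0)
    sds = X_tr.std(axis=0)
    keep = sds > 0                      # drop zero-variance features
    sds_safe = np.where(keep, sds, 1.0)
    Xs = (X_tr - means) / sds_safe
    Xs = Xs[:, keep]
    xs_te = ((x_te - means) / sds_safe)[keep]
    p = Xs.shape[1]
    if p == 0 or len(np.unique(y_tr)) < 2:
        return None

    folds = _stratified_folds(y_tr, inner_k, rng)
    ks = [k for k in grid["n_features"] if 1 <= k <= p]

    # pooled inner-CV predictions per configuration
    scores = {}
    preds = {}
    for fold in folds:
        tr = np.setdiff1d(np.arange(len(y_tr)), fold)
        Xi, yi = Xs[tr], y_tr[tr]
        Xv, yv = Xs[fold], y_tr[fold]
        if len(np.unique(yi)) < 2:
            continue
        wi = _balance_weights(yi)
        rankings = {}
        for selector in grid["selector"]:
            if selector == "f_score":
                rankings[("f_score", None, None)] = _f_score_ranking(Xi, yi)
            elif selector == "rfe":
                for pen in grid["penalty"]:
                    for C in grid["C"]:
                        rankings[("rfe", pen, C)] = _rfe_ranking(Xi, yi, pen, C,
                                                                 wi)
            else:
                raise ValueError(f"unknown selector {selector!r}")
        for selector in grid["selector"]:
            for pen in grid["penalty"]:
                alpha = 1.0 if pen == "l1" else 0.0
                for C in grid["C"]:
                    lam = 1.0 / (C * len(yi))
                    rank = rankings[(selector, None, None)] \
                        if selector == "f_score" else rankings[(selector, pen, C)]
                    for k in ks:
                        feats = rank[:k]
                        b0, coef = _fit_single(Xi[:, feats], yi, lam, alpha, wi)
                        pr = _predict_proba(b0, coef, Xv[:, feats])
                        key = (selector, k, pen, C)
                        preds.setdefault(key, ([], []))
                        preds[key][0].extend(yv)
                        preds[key][1].extend(pr)
    for key, (yy, pp) in preds.items():
        scores[key] = _fast_auc(np.array(yy), np.array(pp))
    if not scores:
        return None
    best = max(scores, key=lambda k: (scores[k], -k[1]))  # ties: fewer features
    selector, k, pen, C = best

    # final refit on the full training fold with the chosen configuration
    alpha = 1.0 if pen == "l1" else 0.0
    lam = 1.0 / (C * len(y_tr))
    w_tr = _balance_weights(y_tr)
    rank = _f_score_ranking(Xs, y_tr) if selector == "f_score" \
        else _rfe_ranking(Xs, y_tr, pen, C, w_tr)
    feats = rank[:k]
    b0, coef = _fit_single(Xs[:, feats], y_tr, lam, alpha, w_tr)
    prob = float(_predict_proba(b0, coef, xs_te[feats][None, :])[0])

    full_coef = np.zeros(len(keep))
    kept_idx = np.flatnonzero(keep)
    full_coef[kept_idx[feats]] = coef
    return prob, full_coef, best


def nested_loocv_logistic(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    grid: dict | None = None,
    inner_k: int = 5,
    seed: int = 0,
) -> NestedCvResult:
    """Nested leave-one-out logistic regression with feature selection.

    *table* is samples x features (pre-filtered, e.g. by read prevalence);
    *labels* binary. The outer loop is leave-one-out; each training fold is
    standardized (parameters from the fold only), zero-variance features
    dropped, and the selection method, panel size, penalty type and
    regularization level chosen by an inner stratified ``inner_k``-fold CV
    maximizing pooled AUC. The reported CV AUC pools the held-out
    probabilities; importance is the mean |coefficient| over outer folds
    (zero when unselected), normalized to sum to one.
    """
    X = table.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    n, p = X.shape
    if grid is None:
        grid = default_grid(p)
    rng = np.random.default_rng(seed)
    probs = np.full(n, np.nan)
    coefs = np.zeros((n, p))
    configs = []
    for i in range(n):
        tr = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        if len(np.unique(y[tr])) < 2:
            warnings.warn(f"outer fold {i}: a class is absent from training; "
                          "fold skipped")
            configs.append(None)
            continue
        fit = _outer_fold_fit(X[tr], y[tr], X[i], grid,
                              np.random.default_rng(rng.integers(2**31)),
                              inner_k=inner_k)
        if fit is None:
            configs.append(None)
            continue
        probs[i], coefs[i], cfg = fit
        configs.append(cfg)
    ok = np.isfinite(probs)
    if not ok.any():
        raise RuntimeError("every outer fold failed")
    cv_auc = _fast_auc(y[ok], probs[ok])
    imp = np.abs(coefs[ok]).mean(axis=0)
    total = imp.sum()
    imp = imp / total if total > 0 else imp
    importance = pd.Series(imp, index=table.columns).sort_values(ascending=False)
    return NestedCvResult(
        cv_auc=float(cv_auc),
        pooled_predictions=pd.Series(probs, index=table.index),
        fold_coefs=pd.DataFrame(coefs, index=table.index, columns=table.columns),
        fold_configs=configs,
        feature_importance=importance,
    )


def leak_probe_auc(
    n: int = 90,
    n_features: int = 7,
    grid: dict | None = None,
    inner_k: int = 5,
    seed: int = 0,
    positive_rate: float = 21 / 90,
) -> float:
    """Leak-detector diagnostic for the nested-CV pipeline.

    Builds a cohort of pure-noise features plus one probe feature that
    equals the class label *only at the held-out sample* of each outer fold
    (training rows of the probe are noise). Because standardization,
    selection and penalty choice use training rows only, the informative
    held-out probe value cannot raise the pooled CV AUC above the null
    band; a leaking pipeline would be caught by an inflated AUC.
    """
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < positive_rate).astype(int)
    if y.sum() in (0, n):
        y[:2] = [0, 1]
    X = rng.normal(size=(n, n_features))
    if grid is None:
        grid = default_grid(n_features)
    probs = np.full(n, np.nan)
    for i in range(n):
        tr = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        x_te = X[i].copy()
        x_te[0] = y[i]                  # probe: held-out value = its label
        fit = _outer_fold_fit(X[tr], y[tr], x_te, grid,
                              np.random.default_rng(rng.integers(2**31)),
                              inner_k=inner_k)
        if fit is not None:
            probs[i] = fit[0]
    ok = np.isfinite(probs)
    return float(_fast_auc(y[ok], probs[ok]))


# ---------------------------------------------------------------------------
# elastic-net panel pipeline
# ---------------------------------------------------------------------------

@dataclass
class PanelConfig:
    """Elastic-net panel pipeline configuration.

    alpha 0.5 weights the LASSO and Ridge penalties equally; observation
    weights compensate class imbalance; 10,000 bootstrap resamples for the
    BCa interval.
    """

    alpha: float = 0.5
    lambda_grid: np.ndarray | None = None
    n_lambda: int = 20
    lambda_min_ratio: float = 1e-3
    class_weighting: bool = True
    n_boot: int = 10_000
    inner_cv: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.n_boot < 1000:
            warnings.warn("n_boot < 1000 is too small for a reliable BCa CI")


@dataclass
class PanelResult:
    kept_features: list
    fold_coefs: pd.DataFrame           # outer folds x features (elastic net)
    selection_predictions: pd.Series   # pooled out-of-fold penalized probs
    refit_coef: pd.Series | None = None
    refit_pvalues: pd.Series | None = None
    cv_auc: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")
    pooled_predictions: pd.Series | None = None
    empty_panel: bool = False
    separation_flag: bool = False


def glmnet_panel_selection(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    config: PanelConfig | None = None,
) -> PanelResult:
    """Stage 1: per-fold elastic-net fits and majority-zero exclusion.

    Outer leave-one-out loop; per fold, observation weights inversely
    proportional to class frequency, the penalty path fit by minimizing
    weighted binomial deviance, and the penalty level chosen by inner
    stratified CV. A feature is excluded iff its coefficient is exactly
    zero in more than half of the outer folds. An empty kept set is
    returned flagged, not raised (a legitimate null outcome).
    """
    cfg = config or PanelConfig()
    X = table.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    n, p = X.shape
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need >= 2 samples per class")
    rng = np.random.default_rng(cfg.seed)
    coefs = np.zeros((n, p))
    probs = np.full(n, np.nan)
    for i in range(n):
        tr = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        Xt, yt = X[tr], y[tr]
        w = _balance_weights(yt) if cfg.class_weighting else np.ones(len(yt))
        Xs, means, sds = _standardize(Xt)
        if cfg.lambda_grid is not None:
            lambdas = np.sort(np.asarray(cfg.lambda_grid, float))[::-1]
        else:
            lambdas = _lambda_path(Xs, yt, w, cfg.alpha, cfg.n_lambda,
                                   cfg.lambda_min_ratio)
        # inner CV: pooled weighted deviance per lambda
        folds = _stratified_folds(yt, cfg.inner_cv,
                                  np.random.default_rng(rng.integers(2**31)))
        dev = np.zeros(len(lambdas))
        for fold in folds:
            itr = np.setdiff1d(np.arange(len(yt)), fold)
            if len(np.unique(yt[itr])) < 2:
                continue
            icepts, cf = enet_logistic_path(Xt[itr], yt[itr], lambdas,
                                            cfg.alpha, w[itr])
            for li in range(len(lambdas)):
                pr = _predict_proba(icepts[li], cf[li], Xt[fold])
                dev[li] += _binomial_deviance(yt[fold], pr, w[fold]) * len(fold)
        best_li = int(np.argmin(dev))
        icepts, cf = enet_logistic_path(Xt, yt, lambdas[: best_li + 1],
                                        cfg.alpha, w)
        coefs[i] = cf[best_li]
        probs[i] = _predict_proba(icepts[best_li], cf[best_li], X[i][None, :])[0]

    zero_frac = (coefs == 0.0).mean(axis=0)
    kept = [f for f, zf in zip(table.columns, zero_frac) if not zf > 0.5]
    return PanelResult(
        kept_features=kept,
        fold_coefs=pd.DataFrame(coefs, index=table.index, columns=table.columns),
        selection_predictions=pd.Series(probs, index=table.index),
        empty_panel=len(kept) == 0,
    )


def refit_logistic_cv_auc(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
) -> tuple:
    """Stage 2: unpenalized logistic refit of the kept panel.

    Reports full-data coefficients with Wald p-values (statsmodels) and the
    pooled leave-one-out CV AUC (each fold refits the unpenalized model;
    the held-out probabilities are concatenated into a single ROC). Under
    perfect separation the coefficients are flagged non-finite but the CV
    AUC is still computed from the pooled predictions.

    Returns ``(cv_auc, coef, pvalues, pooled_predictions, separation_flag)``.
    """
    if table.shape[1] == 0:
        raise ValueError("kept feature set is empty")
    X = table.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    tiny = 1e-8                         # numerically unpenalized ridge
    probs = np.full(n, np.nan)
    for i in range(n):
        tr = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        if len(np.unique(y[tr])) < 2:
            continue
        b0, coef = _fit_single(X[tr], y[tr], tiny, 0.0)
        probs[i] = _predict_proba(b0, coef, X[i][None, :])[0]
    ok = np.isfinite(probs)
    cv_auc = float(_fast_auc(y[ok], probs[ok]))

    separation = False
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            params, pvals = fit.params, fit.pvalues
            if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(params) > 50):
                separation = True
        except Exception:
            separation = True
            params = np.full(X.shape[1] + 1, np.nan)
            pvals = np.full(X.shape[1] + 1, np.nan)
    names = ["intercept"] + list(table.columns)
    coef = pd.Series(np.asarray(params, float), index=names)
    pvalues = pd.Series(np.asarray(pvals, float), index=names)
    return cv_auc, coef, pvalues, pd.Series(probs, index=table.index), separation


def bca_bootstrap_ci(
    predictions,
    labels,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple:
    """95% BCa bootstrap CI for the AUC of pooled predictions.

    Resamples sample indices with replacement; bias correction z0 from the
    fraction of bootstrap statistics below the point estimate (midrank for
    ties), acceleration from jackknife skewness; returns (ci_low, ci_high).
    A degenerate bootstrap distribution collapses the interval to the point
    estimate (with a warning).
    """
    scores = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    theta = _fast_auc(y, scores)
    rng = np.random.default_rng(seed)

    idx = rng.integers(0, n, size=(n_boot, n))
    bs = scores[idx]
    by = y[idx]
    r = rankdata(bs, axis=1)
    n1 = by.sum(axis=1)
    n0 = n - n1
    ranksum = (r * by).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot = (ranksum - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    boot = boot[np.isfinite(boot)]
    if len(boot) == 0:
        raise RuntimeError("no valid bootstrap resample contained both classes")
    if np.all(boot == boot[0]):
        warnings.warn("degenerate bootstrap distribution; CI collapses "
                      "to the point estimate")
        return float(theta), float(theta)

    prop = (np.sum(boot < theta) + 0.5 * np.sum(boot == theta)) / len(boot)
    prop = np.clip(prop, 1.0 / len(boot), 1 - 1.0 / len(boot))
    z0 = sps.norm.ppf(prop)

    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        jack[i] = _fast_auc(y[mask], scores[mask])
        mask[i] = True
    jack = jack[np.isfinite(jack)]
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0

    zal = sps.norm.ppf((1 - level) / 2.0)
    zau = sps.norm.ppf(1 - (1 - level) / 2.0)
    lo_p = sps.norm.cdf(z0 + (z0 + zal) / (1 - a * (z0 + zal)))
    hi_p = sps.norm.cdf(z0 + (z0 + zau) / (1 - a * (z0 + zau)))
    lo, hi = np.quantile(boot, [lo_p, hi_p])
    return float(lo), float(hi)


def elastic_net_panel(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    config: PanelConfig | None = None,
) -> PanelResult:
    """Full elastic-net panel pipeline: selection, refit, CV AUC, BCa CI."""
    cfg = config or PanelConfig()
    result = glmnet_panel_selection(table, labels, cfg)
    if result.empty_panel:
        return result
    y = np.asarray(labels, dtype=int)
    kept_table = table[result.kept_features]
    cv_auc, coef, pvals, pooled, sep = refit_logistic_cv_auc(kept_table, labels)
    ok = pooled.notna()
    lo, hi = bca_bootstrap_ci(pooled[ok].to_numpy(), y[ok.to_numpy()],
                              n_boot=cfg.n_boot, seed=cfg.seed)
    mw = mann_whitney(pooled[ok].to_numpy()[y[ok.to_numpy()] == 1],
                      pooled[ok].to_numpy()[y[ok.to_numpy()] == 0])
    result.refit_coef = coef
    result.refit_pvalues = pvals
    result.cv_auc = cv_auc
    result.ci_low, result.ci_high = lo, hi
    result.p_value = mw.p_value
    result.pooled_predictions = pooled
    result.separation_flag = sep
    if not (lo <= cv_auc <= hi):
        warnings.warn("CV AUC outside its BCa interval (logged, not fatal)")
    return result
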