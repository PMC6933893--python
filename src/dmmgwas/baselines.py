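"""Standard GWAS association methods used as comparison baselines.

All scorers return a :class:`~dmmgwas.scores.ScoreVector`:

* ``univariate_wald`` — per-SNP simple linear (or logistic) regression
  with an intercept, Wald p-values.  No confounder handling, no epistasis.
* ``bh_adjust`` — Benjamini-Hochberg step-up FDR adjustment (reporting
  thresholds only; ROC ranking uses raw p-values, which BH, being
  monotone, would not change).
* ``lmm_scan`` — EMMAX-style linear mixed model: kinship from standardized
  genotypes, null-model variance components by REML on the eigenbasis,
  per-SNP generalized-least-squares Wald tests with the components fixed.
* ``lasso_scores`` / ``adaptive_lasso_scores`` — coordinate-descent L1
  paths over a log-spaced grid; a SNP's strength is the largest penalty at
  which its coefficient is active, so the path order is the ROC sweep.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Ridge, lasso_path
from statsmodels.stats.multitest import multipletests

from .scores import ScoreVector

__all__ = ["univariate_wald", "bh_adjust", "lmm_scan", "lasso_scores",
           "adaptive_lasso_scores", "default_lambda_grid"]


def default_lambda_grid(num: int = 50) -> np.ndarray:
    """Penalty grid: ``num`` points even in log10-space from 1e-5 to 1e5."""
    return np.logspace(-5, 5, num)


def _standardize(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


# ---------------------------------------------------------------------------
# univariate Wald testing

def _wald_continuous(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc ** 2).sum(axis=0)
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    ok = sxx > 0
    pvals = np.ones(X.shape[1])
    slope = np.zeros_like(sxx)
    slope[ok] = sxy[ok] / sxx[ok]
    rss = syy - slope ** 2 * sxx
    rss = np.clip(rss, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = rss / (n - 2) / sxx
        tstat = slope / np.sqrt(se2)
    # rss = 0 with nonzero slope is a perfect fit -> t = inf -> p = 0;
    # 0/0 (zero slope, zero rss) -> t = 0
    tstat = np.nan_to_num(tstat, nan=0.0, posinf=np.inf, neginf=-np.inf)
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df=n - 2)
    return pvals


def _wald_binary(X: np.ndarray, y: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """Per-SNP logistic regression (intercept + slope), Newton iterations
    vectorized across all SNPs at once."""
    n, p = X.shape
    a = np.full(p, float(np.log((y.mean() + 1e-9) / (1 - y.mean() + 1e-9))))
    b = np.zeros(p)
    for _ in range(n_iter):
        eta = np.clip(a[None, :] + X * b[None, :], -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        res = mu - y[:, None]
        ga = res.sum(axis=0)
        gb = (res * X).sum(axis=0)
        s = mu * (1.0 - mu)
        haa = s.sum(axis=0)
        hab = (s * X).sum(axis=0)
        hbb = (s * X * X).sum(axis=0)
        det = haa * hbb - hab ** 2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        da = (hbb * ga - hab * gb) / det
        db = (haa * gb - hab * ga) / det
        a -= np.clip(da, -5, 5)
        b -= np.clip(db, -5, 5)
    eta = np.clip(a[None, :] + X * b[None, :], -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    s = mu * (1.0 - mu)
    haa = s.sum(axis=0)
    hab = (s * X).sum(axis=0)
    hbb = (s * X * X).sum(axis=0)
    det = haa * hbb - hab ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(haa / det)
        z = b / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals[~np.isfinite(z)] = 1.0
    pvals[X.std(axis=0) == 0] = 1.0
    return np.clip(pvals, 0.0, 1.0)


def univariate_wald(X: np.ndarray, y: np.ndarray,
                    task_kind: str = "continuous") -> ScoreVector:
    """Per-SNP Wald p-values; constant SNP columns get p = 1 by convention."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(y == y[0]):
        raise ValueError("phenotype is constant")
    if task_kind == "continuous":
        pvals = _wald_continuous(X, y)
    elif task_kind == "binary":
        pvals = _wald_binary(X, y)
    else:
        raise ValueError(f"unknown task_kind {task_kind!r}")
    return ScoreVector(scores=pvals, method="UT",
                       orientation="lower_is_associated")


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (clipped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim != 1 or pvals.size == 0:
        raise ValueError("pvals must be a non-empty 1-D array")
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# linear mixed model (EMMAX-style)

def _reml_neg_loglik(h2: float, lam: np.ndarray, yt: np.ndarray,
                     zt: np.ndarray) -> float:
    """Negative REML log-likelihood (total variance profiled out) for the
    null model y = mu + g + e on the kinship eigenbasis."""
    n = yt.shape[0]
    w = h2 * lam + (1.0 - h2)
    zw = zt / w
    ztz = float(zt @ zw)
    bhat = float(zw @ yt) / ztz
    res = yt - zt * bhat
    rss = float(res @ (res / w))
    c = 1  # intercept only
    return 0.5 * ((n - c) * np.log(rss) + np.sum(np.log(w)) + np.log(ztz))


def lmm_scan(X: np.ndarray, y: np.ndarray, task_kind: str = "continuous",
             kinship: np.ndarray | None = None) -> ScoreVector:
    """Mixed-model association scan.

    Kinship K = X~ X~' / p from column-standardized genotypes; heritability
    ratio estimated once by REML on the eigendecomposition of K; per-SNP
    GLS Wald t-tests with the variance components held fixed.  Binary
    phenotypes are handled as 0/1 Gaussian responses (linear probability),
    recorded in the metadata.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if kinship is None:
        Xs = _standardize(X)
        K = Xs @ Xs.T / p
    else:
        K = np.asarray(kinship, dtype=float).copy()
    K += 1e-8 * np.eye(n)  # jitter
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-6:
        raise ValueError("kinship matrix is not PSD even after jitter")
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    zt = U.T @ np.ones(n)
    opt = minimize_scalar(_reml_neg_loglik, bounds=(1e-6, 1 - 1e-6),
                          args=(lam, yt, zt), method="bounded",
                          options={"xatol": 1e-8})
    h2 = float(opt.x)
    w = h2 * lam + (1.0 - h2)
    sw = np.sqrt(w)
    a = yt / sw
    z0 = zt / sw
    C = (U.T @ X) / sw[:, None]
    # project out the (rotated, weighted) intercept, then per-SNP slope tests
    z0n2 = float(z0 @ z0)
    a_perp = a - z0 * (float(z0 @ a) / z0n2)
    proj = (z0 @ C) / z0n2
    C_perp = C - np.outer(z0, proj)
    cc = (C_perp ** 2).sum(axis=0)
    ca = C_perp.T @ a_perp
    aa = float(a_perp @ a_perp)
    ok = cc > 1e-12
    pvals = np.ones(p)
    slope = np.zeros(p)
    slope[ok] = ca[ok] / cc[ok]
    rss = np.clip(aa - slope ** 2 * cc, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = slope / np.sqrt(rss / (n - 2) / cc)
    tstat[~np.isfinite(tstat)] = 0.0
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df=n - 2)
    meta = {"h2": h2, "gaussian_approx": task_kind == "binary"}
    return ScoreVector(scores=pvals, method="LMM",
                       orientation="lower_is_associated", metadata=meta)


# ---------------------------------------------------------------------------
# L1 paths

def _path_activation_strengths(coefs: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Per-SNP strength = largest penalty at which the coefficient is
    nonzero (0 for SNPs never active)."""
    active = np.abs(coefs) > 0  # (p, n_alphas)
    strengths = np.zeros(coefs.shape[0])
    any_active = active.any(axis=1)
    first = active.argmax(axis=1)  # alphas sorted descending by lasso_path
    strengths[any_active] = alphas[first[any_active]]
    return strengths


def lasso_scores(X: np.ndarray, y: np.ndarray,
                 lambda_grid: np.ndarray | None = None,
                 penalty_weights: np.ndarray | None = None,
                 method_label: str = "LASSO") -> ScoreVector:
    """L1 path over the penalty grid on standardized genotypes.

    Penalty convention is scikit-learn's: (1/2n)||y - Xb||^2 + alpha ||b||_1.
    ``penalty_weights`` (optional, for the adaptive variant) rescales the
    penalty per feature via the standard column-scaling substitution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    Xs = _standardize(X)
    if penalty_weights is not None:
        pw = np.asarray(penalty_weights, dtype=float)
        Xs = Xs / pw  # b_j = b'_j / pw_j; |b'| penalized uniformly
    yc = y - y.mean()
    n_noncvg = 0
    if np.all(grid == 0):
        coef, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
        coefs = coef[:, None]
        alphas = np.array([0.0])
    else:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always", ConvergenceWarning)
            alphas, coefs, _ = lasso_path(Xs, yc, alphas=grid, max_iter=2000,
                                          tol=1e-4)
            n_noncvg = sum(issubclass(w.category, ConvergenceWarning)
                           for w in wlist)
    strengths = _path_activation_strengths(coefs, alphas)
    meta = {"lambda_grid": np.asarray(alphas),
            "coef_path": coefs,
            "n_nonconverged": n_noncvg}
    if penalty_weights is not None:
        meta["penalty_weights"] = pw
    return ScoreVector(scores=strengths, method=method_label,
                       orientation="higher_is_associated", metadata=meta)


def adaptive_lasso_scores(X: np.ndarray, y: np.ndarray,
                          lambda_grid: np.ndarray | None = None,
                          ridge_alpha: float = 1.0,
                          xi: float = 1e-6,
                          penalty_weights: np.ndarray | None = None) -> ScoreVector:
    """Adaptive Lasso: per-feature penalties 1/(|b_ridge| + xi) from a ridge
    initial fit, then the weighted L1 path over the same grid."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if penalty_weights is None:
        Xs = _standardize(X)
        init = Ridge(alpha=ridge_alpha, fit_intercept=True).fit(Xs, y)
        penalty_weights = 1.0 / (np.abs(init.coef_) + xi)
    sv = lasso_scores(X, y, lambda_grid=lambda_grid,
                      penalty_weights=penalty_weights, method_label="AL")
    return sv
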