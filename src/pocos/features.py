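"""Representative-genotype features of locus sets and significance filters.

Each locus set P yields one feature per sample: the fraction of its loci
harboring their genotype of interest, h(P, s) = sum_{c in P} M(c, s) / |P|,
a value in [0, 1]. Two filters reduce the feature set before model fitting:

* a two-sample Kolmogorov-Smirnov test of the case vs control distribution
  of each feature (exact p-values below 25 samples per class, asymptotic
  above);
* Wald p-values of the coefficients in one joint logistic regression of
  the phenotype on all features. Because the joint fit is ill-posed when
  there are more features than samples, a small L2 stabilizer (1e-4, not
  applied to the intercept) is always added; the fit is flagged whenever
  q > n/2.

Features with p <= alpha are retained. Set p-values are compared to alpha
raw by default; Bonferroni correction is available as a switch and is the
default for individual-locus baselines elsewhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import DEFAULTS
from .errors import ConvergenceError, UndefinedTestError
from .genotype_models import BinaryProfileSet
from .poco_search import PoCo, PoCoCollection

logger = logging.getLogger(__name__)


def representative_genotype(poco: PoCo, profiles: BinaryProfileSet) -> np.ndarray:
    """h(P, .) over the samples of ``profiles.M`` (denominator |P|)."""
    if len(poco.loci) == 0:
        raise ValueError("cannot compute a representative genotype of an empty set")
    idx = [profiles.locus_ids.index(lid) for lid in poco.loci]
    return profiles.M[idx].mean(axis=0)


def feature_matrix(
    collection: PoCoCollection, profiles: BinaryProfileSet, M: np.ndarray | None = None
) -> np.ndarray:
    """Samples x sets matrix H with H[s, j] = h(P_j, s).

    ``M`` defaults to the training matrix stored in ``profiles``; pass the
    binarization of a held-out sample subset to featurize test samples.
    """
    M = profiles.M if M is None else np.asarray(M, dtype=bool)
    index = {lid: i for i, lid in enumerate(profiles.locus_ids)}
    cols = []
    for poco in collection:
        idx = [index[lid] for lid in poco.loci]
        cols.append(M[idx].mean(axis=0))
    if not cols:
        return np.empty((M.shape[1], 0))
    return np.column_stack(cols)


def _check_classes(phenotype: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    phenotype = np.asarray(phenotype)
    case = phenotype == 1
    if not case.any() or case.all():
        raise UndefinedTestError("feature filtering needs both phenotype classes")
    return case, ~case


def ks_pvalues(H: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """Two-sided two-sample KS p-value per feature column."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    case, ctrl = _check_classes(phenotype)
    method = "exact" if min(case.sum(), ctrl.sum()) < 25 else "asymp"
    out = np.empty(H.shape[1])
    for j in range(H.shape[1]):
        a, b = H[case, j], H[ctrl, j]
        if np.ptp(H[:, j]) == 0:  # constant feature: statistic 0, p 1
            out[j] = 1.0
            continue
        out[j] = stats.ks_2samp(a, b, alternative="two-sided", method=method).pvalue
    return out


def filter_by_ks(
    H: np.ndarray,
    phenotype: np.ndarray,
    alpha: float = 0.05,
    correction: str = "raw",
) -> tuple[np.ndarray, np.ndarray]:
    """KS filter: returns (boolean keep mask, p-values)."""
    p = ks_pvalues(H, phenotype)
    return _apply_threshold(p, alpha, correction), p


def _apply_threshold(p: np.ndarray, alpha: float, correction: str) -> np.ndarray:
    if correction == "bonferroni":
        p = np.minimum(p * len(p), 1.0)
    elif correction != "raw":
        raise ValueError("correction must be 'raw' or 'bonferroni'")
    return p <= alpha


def _ridge_logistic_wald(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton fit of logistic regression with an L2 stabilizer.

    The intercept (first column) is unpenalized. Returns coefficients and
    Wald standard errors from the inverse penalized Hessian.
    """
    n, k = X.shape
    penalty = np.full(k, 2.0 * ridge)
    penalty[0] = 0.0
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = p * (1.0 - p)
        grad = X.T @ (y - p) - penalty * beta
        hess = (X.T * w) @ X + np.diag(penalty)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise ConvergenceError(
            f"joint filtering regression did not converge in {max_iter} iterations"
        )
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = p * (1.0 - p)
    hess = (X.T * w) @ X + np.diag(penalty)
    cov = np.linalg.pinv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return beta, se


def regression_pvalues(
    H: np.ndarray,
    phenotype: np.ndarray,
    ridge: float = DEFAULTS.regression_filter_ridge,
) -> np.ndarray:
    """Per-feature Wald p-values from one joint logistic regression."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    _check_classes(phenotype)
    y = np.asarray(phenotype, dtype=float)
    n, q = H.shape
    if q == 0:
        return np.empty(0)
    if q > n / 2:
        logger.info(
            "joint filtering regression with q=%d features on n=%d samples; "
            "L2-stabilized fit flagged",
            q,
            n,
        )
    X = np.column_stack([np.ones(n), H])
    beta, se = _ridge_logistic_wald(X, y, ridge)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se[1:] > 0, beta[1:] / se[1:], 0.0)
    return 2.0 * stats.norm.sf(np.abs(z))


def filter_by_regression(
    H: np.ndarray,
    phenotype: np.ndarray,
    alpha: float = 0.05,
    ridge: float = DEFAULTS.regression_filter_ridge,
    correction: str = "raw",
) -> tuple[np.ndarray, np.ndarray]:
    """Joint-regression filter: returns (boolean keep mask, p-values)."""
    p = regression_pvalues(H, phenotype, ridge=ridge)
    return _apply_threshold(p, alpha, correction), p
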