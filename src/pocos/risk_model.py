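"""Risk models over locus-set features, nested cross-validation, baselines.

The risk classifier is L1-regularized logistic regression,

    min_beta  -log p(f | H; beta) + lambda * ||beta||_1,

with an unpenalized intercept; the penalty weight lambda (default 0.001)
controls the number of features retained in the final model. Performance
is measured by the area under the ROC curve, computed by the Mann-Whitney
identity (ties counted 1/2).

Evaluation uses nested stratified K-fold cross-validation: genotype-model
selection, locus-set discovery, feature construction and filtering all run
on training folds only; the filtering threshold alpha and penalty lambda
are chosen on inner folds by mean AUC (ties resolved toward the sparser
model). The fold randomization is repeated (default 5 times) with recorded
seeds and the AUC is reported as mean +/- sd over repeats.

Baselines sharing the same evaluation harness:

* individual loci — additive minor-allele coding of loci passing a
  Bonferroni-corrected single-locus association threshold, then the same
  L1 classifier;
* polygenic score — PS_alpha(s) = sum_{c in L} gamma(c) * g(c, s), where L
  is the set of loci with training association p < alpha and gamma(c) is
  the log-odds coefficient of a univariate logistic regression on the
  additive coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, KFold

from .config import DEFAULTS
from .errors import AlignmentError, ConvergenceError, UndefinedTestError
from .features import feature_matrix, ks_pvalues, regression_pvalues
from .genotype_models import select_models
from .gwas_io import (
    MISSING,
    GwasDataset,
    allelic_association_pvalues,
)
from .hetnet import HeterogeneousNetwork, reachability_for
from .poco_search import discover_pocos

# ---------------------------------------------------------------------------
# Core model
# ---------------------------------------------------------------------------


@dataclass
class RiskModel:
    """A fitted sparse logistic risk model."""

    coef: np.ndarray
    intercept: float
    lam: float

    @property
    def nonzero(self) -> int:
        return int(np.count_nonzero(self.coef))

    @property
    def n_features(self) -> int:
        return len(self.coef)


def _nll_and_grad(X: np.ndarray, y: np.ndarray, beta: np.ndarray):
    """Total logistic negative log-likelihood and its gradient."""
    eta = X @ beta
    sign = 2.0 * y - 1.0
    nll = np.logaddexp(0.0, -sign * eta).sum()
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    return nll, X.T @ (p - y)


def fit_l1_logistic(
    H: np.ndarray,
    phenotype: np.ndarray,
    lam: float = DEFAULTS.lasso_lambda,
    tol: float = 1e-6,
    max_iter: int = 5_000,
) -> RiskModel:
    """Fit the L1-penalized logistic risk model.

    The objective is the total negative log-likelihood plus
    ``lam * ||beta||_1`` with an unpenalized intercept (``lam=0`` reduces to
    an ordinary logistic fit). Solved exactly by recasting each penalized
    coefficient as the difference of two non-negative parts, which turns
    the objective into a smooth bound-constrained problem handled by
    L-BFGS-B; coefficients at the bound are exact zeros. Non-convergence
    raises.
    """
    from scipy.optimize import minimize

    H = np.atleast_2d(np.asarray(H, dtype=float))
    y = np.asarray(phenotype, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if H.shape[1] == 0:
        raise ValueError("at least one feature is required")
    if len(np.unique(y)) < 2:
        raise UndefinedTestError("model fitting needs both phenotype classes")

    n, q = H.shape
    X = np.column_stack([np.ones(n), H])

    def solve(x0=None):
        if lam == 0:
            res = minimize(
                lambda b: _nll_and_grad(X, y, b),
                np.zeros(q + 1) if x0 is None else x0,
                jac=True,
                method="L-BFGS-B",
                options=dict(maxiter=max_iter, ftol=1e-14, gtol=tol * 1e-2),
            )
            return res.x, res

        def obj(theta):
            b = np.empty(q + 1)
            b[0] = theta[0]
            b[1:] = theta[1 : q + 1] - theta[q + 1 :]
            nll, g = _nll_and_grad(X, y, b)
            grad = np.empty(2 * q + 1)
            grad[0] = g[0]
            grad[1 : q + 1] = g[1:] + lam
            grad[q + 1 :] = -g[1:] + lam
            return nll + lam * theta[1:].sum(), grad

        res = minimize(
            obj,
            np.zeros(2 * q + 1) if x0 is None else x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(None, None)] + [(0.0, None)] * (2 * q),
            options=dict(maxiter=max_iter, ftol=1e-14, gtol=tol * 1e-2),
        )
        b = np.empty(q + 1)
        b[0] = res.x[0]
        b[1:] = res.x[1 : q + 1] - res.x[q + 1 :]
        return b, res

    def kkt_residual(b):
        # stationarity of NLL + lam*||b[1:]||_1 (intercept unpenalized)
        _, g = _nll_and_grad(X, y, b)
        r = abs(g[0])
        for j in range(1, q + 1):
            if b[j] != 0:
                r = max(r, abs(g[j] + lam * np.sign(b[j])))
            else:
                r = max(r, max(abs(g[j]) - lam, 0.0))
        return r

    # A successful status means the objective is converged to machine
    # precision (ftol=1e-14). The optimizer can also stop with a
    # line-search failure on an already-converged iterate; those stops are
    # retried once and then accepted only if the KKT stationarity residual
    # is small on the total-NLL gradient scale.
    beta, res = solve()
    if not res.success:
        beta, res = solve(x0=res.x)
    kkt_tol = max(tol * n, 5e-3)
    if not res.success and kkt_residual(beta) > kkt_tol:
        raise ConvergenceError(
            f"L1 logistic fit did not converge (lam={lam}, n={n}, q={q}, "
            f"KKT residual {kkt_residual(beta):.3g} > {kkt_tol:.3g}): "
            f"{res.message}"
        )
    return RiskModel(coef=beta[1:].copy(), intercept=float(beta[0]), lam=lam)


def predict_risk(model: RiskModel, H: np.ndarray) -> np.ndarray:
    """Per-sample case probability under the logistic link."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if H.shape[1] != model.n_features:
        raise AlignmentError(
            f"model has {model.n_features} features, input has {H.shape[1]}"
        )
    eta = H @ model.coef + model.intercept
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -709, 709)))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney identity (ties -> 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    case = labels == 1
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedTestError("AUC needs both classes")
    ranks = rankdata(scores)
    return float((ranks[case].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# Polygenic score
# ---------------------------------------------------------------------------


@dataclass
class PolygenicModel:
    """Additive polygenic score: loci below the training p threshold and
    their univariate log-odds effect sizes."""

    alpha: float
    locus_ids: list[str]
    gamma: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.locus_ids)


def _additive_coding(genotypes: np.ndarray, minor_is_allele2: np.ndarray) -> np.ndarray:
    """Minor-allele copy counts as float; missing genotypes contribute 0."""
    g = genotypes
    coded = np.where(minor_is_allele2[:, None], g, 2 - g).astype(float)
    coded[g == MISSING] = 0.0
    return coded


def univariate_logistic_effects(
    G: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-9
) -> np.ndarray:
    """Slope of a univariate logistic regression for each row of ``G``.

    A vectorized Newton solver (each locus is a 2-parameter problem). Loci
    with a degenerate design (constant genotype) get a slope of 0; diverging
    slopes under separation are capped at |30|. Agreement with statsmodels
    is covered by tests.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    y = np.asarray(y, dtype=float)
    L, n = G.shape
    a = np.zeros(L)
    b = np.zeros(L)
    active = np.ptp(G, axis=1) > 0
    for _ in range(max_iter):
        eta = np.clip(a[:, None] + b[:, None] * G, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        r = y[None, :] - p
        w = p * (1 - p)
        g0 = r.sum(axis=1)
        g1 = (r * G).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * G).sum(axis=1)
        h11 = (w * G * G).sum(axis=1)
        det = h00 * h11 - h01 * h01
        ok = active & (det > 1e-12)
        if not ok.any():
            break
        da = np.where(ok, (h11 * g0 - h01 * g1) / np.where(ok, det, 1.0), 0.0)
        db = np.where(ok, (h00 * g1 - h01 * g0) / np.where(ok, det, 1.0), 0.0)
        a += da
        b += db
        b = np.clip(b, -30, 30)
        if max(np.abs(da).max(), np.abs(db).max()) < tol:
            break
    return b


def polygenic_score(
    train: GwasDataset, test: GwasDataset, alpha: float
) -> tuple[PolygenicModel, np.ndarray]:
    """Fit the polygenic score on ``train`` and score ``test`` samples.

    ``train`` and ``test`` must share the locus universe (same loci, same
    order). Raises if no locus has training p < alpha.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if train.locus_ids != test.locus_ids:
        raise AlignmentError("train and test must share the locus universe")
    p = allelic_association_pvalues(train)
    sel = np.flatnonzero(p < alpha)
    if sel.size == 0:
        raise UndefinedTestError(
            f"no locus reaches p < {alpha}; increase alpha"
        )
    G_train = _additive_coding(train.genotypes[sel], train.minor_is_allele2[sel])
    gamma = univariate_logistic_effects(G_train, train.phenotype)
    G_test = _additive_coding(test.genotypes[sel], train.minor_is_allele2[sel])
    scores = gamma @ G_test
    model = PolygenicModel(
        alpha=alpha, locus_ids=[train.locus_ids[i] for i in sel], gamma=gamma
    )
    return model, scores


# ---------------------------------------------------------------------------
# Pipeline stages (everything fit on training samples only)
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """What to run inside each cross-validation training fold."""

    method: str  # 'netpoco' | 'free' | 'loci' | 'prs'
    filter: str = "ks"  # 'ks' | 'regression' (locus-set methods only)
    network: HeterogeneousNetwork | None = None
    alpha_grid: tuple = DEFAULTS.alpha_grid
    lambda_grid: tuple = DEFAULTS.lambda_grid
    coverage_fraction: float = DEFAULTS.coverage_fraction
    #: multiple-testing handling of the individual-locus baseline's
    #: association filter ('bonferroni' or 'raw'); locus-set p-values are
    #: always compared raw
    locus_correction: str = "bonferroni"

    def __post_init__(self):
        if self.method not in ("netpoco", "free", "loci", "prs"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "netpoco" and self.network is None:
            raise ValueError("method 'netpoco' requires a network")
        if self.filter not in ("ks", "regression"):
            raise ValueError(f"unknown filter {self.filter!r}")


class _PocoStage:
    """Locus-set pipeline fitted on one training sample set."""

    def __init__(self, ds_train: GwasDataset, config: PipelineConfig, reach):
        self.profiles = select_models(ds_train)
        pool = None
        if config.method == "netpoco":
            in_net = set(config.network.locus_ids)
            pool = [lid for lid in self.profiles.locus_ids if lid in in_net]
        self.collection = discover_pocos(
            ds_train,
            self.profiles,
            coverage_fraction=config.coverage_fraction,
            reach=reach if config.method == "netpoco" else None,
            candidate_pool=pool,
        )
        self.H_train = feature_matrix(self.collection, self.profiles)
        if self.H_train.shape[1] == 0:
            self.pvals = np.empty(0)
        elif config.filter == "ks":
            self.pvals = ks_pvalues(self.H_train, ds_train.phenotype)
        else:
            self.pvals = regression_pvalues(self.H_train, ds_train.phenotype)
        self.y_train = ds_train.phenotype

    def columns(self, alpha: float) -> np.ndarray:
        return np.flatnonzero(self.pvals <= alpha)

    def features_for(self, ds: GwasDataset) -> np.ndarray:
        M = self.profiles.binarize_dataset(ds)
        return feature_matrix(self.collection, self.profiles, M=M)

    def prepare(self, ds: GwasDataset):
        return self.features_for(ds)


class _LociStage:
    """Individual-locus baseline: Bonferroni-filtered additive features."""

    def __init__(self, ds_train: GwasDataset, config: PipelineConfig):
        p = np.nan_to_num(allelic_association_pvalues(ds_train), nan=1.0)
        if config.locus_correction == "bonferroni":
            self.p_adj = np.minimum(p * ds_train.n_loci, 1.0)
        elif config.locus_correction == "raw":
            self.p_adj = p
        else:
            raise ValueError("locus_correction must be 'bonferroni' or 'raw'")
        self.orientation = ds_train.minor_is_allele2
        self.H_train = _additive_coding(ds_train.genotypes, self.orientation).T
        self.y_train = ds_train.phenotype

    def columns(self, alpha: float) -> np.ndarray:
        return np.flatnonzero(self.p_adj <= alpha)

    def features_for(self, ds: GwasDataset) -> np.ndarray:
        return _additive_coding(ds.genotypes, self.orientation).T

    def prepare(self, ds: GwasDataset):
        return self.features_for(ds)


class _PrsStage:
    """Polygenic-score baseline; effect sizes memoized across alphas."""

    def __init__(self, ds_train: GwasDataset, config: PipelineConfig):
        self.ds_train = ds_train
        self.p = allelic_association_pvalues(ds_train)
        self.orientation = ds_train.minor_is_allele2
        self._gamma = np.full(ds_train.n_loci, np.nan)

    def loci_for(self, alpha: float) -> np.ndarray:
        return np.flatnonzero(self.p < alpha)

    def _effects(self, sel: np.ndarray) -> np.ndarray:
        todo = sel[np.isnan(self._gamma[sel])]
        if todo.size:
            G = _additive_coding(
                self.ds_train.genotypes[todo], self.orientation[todo]
            )
            self._gamma[todo] = univariate_logistic_effects(
                G, self.ds_train.phenotype
            )
        return self._gamma[sel]

    def prepare(self, ds: GwasDataset):
        return _additive_coding(ds.genotypes, self.orientation)

    def score(self, coded: np.ndarray, alpha: float) -> np.ndarray | None:
        sel = self.loci_for(alpha)
        if sel.size == 0:
            return None
        gamma = self._effects(sel)
        return gamma @ coded[sel]


def _build_stage(ds_train: GwasDataset, config: PipelineConfig, reach):
    if config.method in ("netpoco", "free"):
        return _PocoStage(ds_train, config, reach)
    if config.method == "loci":
        return _LociStage(ds_train, config)
    return _PrsStage(ds_train, config)


def _eval_config(stage, prepared, n_val, alpha, lam):
    """(scores, model_size) of one config on held-out samples; None if invalid.

    ``prepared`` is the output of ``stage.prepare`` on the held-out samples
    (computed once per fold, shared across the configuration grid).
    """
    if isinstance(stage, _PrsStage):
        scores = stage.score(prepared, alpha)
        if scores is None:
            return None
        return scores, len(stage.loci_for(alpha))
    cols = stage.columns(alpha)
    if cols.size == 0:
        return np.full(n_val, 0.5), 0
    model = fit_l1_logistic(stage.H_train[:, cols], stage.y_train, lam)
    scores = predict_risk(model, prepared[:, cols])
    return scores, model.nonzero


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------


@dataclass
class CVConfig:
    n_folds: int = DEFAULTS.n_folds
    n_inner_folds: int = DEFAULTS.n_folds
    n_repeats: int = DEFAULTS.n_repeats
    stratified: bool = True
    seed: int = 0

    def repeat_seed(self, repeat: int) -> int:
        return int(self.seed + 1000 * repeat) % (2**31 - 1)


@dataclass
class CVResult:
    method: str
    repeat_aucs: list[float]
    mean_auc: float
    sd_auc: float
    mean_model_size: float
    oof_scores: np.ndarray  # (n_repeats, n_samples)
    chosen_configs: list  # per (repeat, outer fold)
    seeds: list[int]
    failed_folds: int = 0


def _splitter(cv: CVConfig, n_splits: int, seed: int):
    cls = StratifiedKFold if cv.stratified else KFold
    return cls(n_splits=n_splits, shuffle=True, random_state=seed)


def _configs(pipeline: PipelineConfig):
    if pipeline.method == "prs":
        return [(a, None) for a in pipeline.alpha_grid]
    return [(a, l) for a in pipeline.alpha_grid for l in pipeline.lambda_grid]


def _pick_best(config_scores: dict) -> tuple:
    """Best mean inner AUC; ties to the sparser model (larger lam, smaller alpha)."""
    best, best_key = None, None
    for (alpha, lam), aucs in config_scores.items():
        if not aucs:
            continue
        mean = float(np.mean(aucs))
        key = (mean, lam if lam is not None else 0.0, -alpha)
        if best_key is None or key > best_key:
            best_key, best = key, (alpha, lam)
    return best


def nested_cv(
    dataset: GwasDataset,
    pipeline: PipelineConfig,
    cv: CVConfig | None = None,
) -> CVResult:
    """Nested stratified cross-validation of one pipeline.

    Outer folds estimate performance; inner folds select (alpha, lambda) by
    mean AUC. All discovery and selection steps see training samples only.
    Out-of-fold predictions are pooled into one AUC per repeat.
    """
    cv = cv or CVConfig()
    y = dataset.phenotype
    n = dataset.n_samples
    reach = None
    if pipeline.method == "netpoco":
        reach = reachability_for(pipeline.network, dataset.locus_ids)

    oof = np.full((cv.n_repeats, n), np.nan)
    repeat_aucs: list[float] = []
    chosen: list = []
    sizes: list[float] = []
    seeds: list[int] = []
    failed = 0

    for r in range(cv.n_repeats):
        seed_r = cv.repeat_seed(r)
        seeds.append(seed_r)
        outer = _splitter(cv, cv.n_folds, seed_r)
        ok_folds = 0
        for fold, (tr, te) in enumerate(outer.split(np.zeros(n), y)):
            ds_tr = dataset.subset_samples(tr)
            y_tr = y[tr]

            config_scores = {c: [] for c in _configs(pipeline)}
            inner = _splitter(cv, cv.n_inner_folds, seed_r + fold + 1)
            for itr, ival in inner.split(np.zeros(len(tr)), y_tr):
                stage = _build_stage(ds_tr.subset_samples(itr), pipeline, reach)
                prepared = stage.prepare(ds_tr.subset_samples(ival))
                for cfg in config_scores:
                    out = _eval_config(stage, prepared, len(ival), *cfg)
                    if out is None:
                        continue
                    scores, _ = out
                    config_scores[cfg].append(auc(scores, y_tr[ival]))
            best = _pick_best(config_scores)
            if best is None:
                # no valid configuration (e.g. PRS with an empty locus set
                # at every alpha): constant predictions for this fold
                oof[r, te] = 0.5
                chosen.append(None)
                sizes.append(0.0)
                failed += 1
                continue

            stage = _build_stage(ds_tr, pipeline, reach)
            prepared = stage.prepare(dataset.subset_samples(te))
            out = _eval_config(stage, prepared, len(te), *best)
            if out is None:
                oof[r, te] = 0.5
                chosen.append(None)
                sizes.append(0.0)
                failed += 1
                continue
            scores, size = out
            oof[r, te] = scores
            chosen.append(best)
            sizes.append(float(size))
            ok_folds += 1
        repeat_aucs.append(auc(oof[r], y))

    return CVResult(
        method=pipeline.method,
        repeat_aucs=repeat_aucs,
        mean_auc=float(np.mean(repeat_aucs)),
        sd_auc=float(np.std(repeat_aucs, ddof=1)) if len(repeat_aucs) > 1 else 0.0,
        mean_model_size=float(np.mean(sizes)) if sizes else 0.0,
        oof_scores=oof,
        chosen_configs=chosen,
        seeds=seeds,
        failed_folds=failed,
    )


def lambda_sweep(
    dataset: GwasDataset,
    pipeline: PipelineConfig,
    lambdas: Sequence[float] = DEFAULTS.lambda_grid,
    alpha: float = 0.05,
    cv: CVConfig | None = None,
) -> dict[float, dict]:
    """Out-of-fold AUC as a function of the L1 penalty at a fixed alpha.

    No inner selection: the feature filter threshold is fixed and each
    lambda is evaluated on the same outer folds. Returns, per lambda, the
    pooled AUC per repeat, its mean, and the mean nonzero-coefficient count.
    """
    if pipeline.method == "prs":
        raise ValueError("the polygenic score has no lambda parameter")
    cv = cv or CVConfig()
    y = dataset.phenotype
    n = dataset.n_samples
    reach = None
    if pipeline.method == "netpoco":
        reach = reachability_for(pipeline.network, dataset.locus_ids)

    oof = {lam: np.full((cv.n_repeats, n), np.nan) for lam in lambdas}
    sizes = {lam: [] for lam in lambdas}
    for r in range(cv.n_repeats):
        seed_r = cv.repeat_seed(r)
        outer = _splitter(cv, cv.n_folds, seed_r)
        for tr, te in outer.split(np.zeros(n), y):
            stage = _build_stage(dataset.subset_samples(tr), pipeline, reach)
            prepared = stage.prepare(dataset.subset_samples(te))
            for lam in lambdas:
                scores, size = _eval_config(stage, prepared, len(te), alpha, lam)
                oof[lam][r, te] = scores
                sizes[lam].append(float(size))
    result = {}
    for lam in lambdas:
        aucs = [auc(oof[lam][r], y) for r in range(cv.n_repeats)]
        result[lam] = {
            "repeat_aucs": aucs,
            "mean_auc": float(np.mean(aucs)),
            "mean_model_size": float(np.mean(sizes[lam])),
        }
    return result
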