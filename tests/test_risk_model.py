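import numpy as np
import pytest
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

import pocos.risk_model as rm
from pocos import (
    CVConfig,
    PipelineConfig,
    auc,
    fit_l1_logistic,
    nested_cv,
    polygenic_score,
    predict_risk,
)
from pocos.errors import AlignmentError, UndefinedTestError
from pocos.risk_model import RiskModel, univariate_logistic_effects
from pocos.synthetic_data import PlantedModule, SimulationSpec, simulate_cohort
from conftest import make_dataset


def toy_problem(rng, n=300, q=4, strength=2.0):
    H = rng.random((n, q))
    eta = -1.0 + strength * H[:, 0]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return H, y


class TestL1Fit:
    def test_huge_lambda_zeroes_all_coefficients(self, rng):
        H, y = toy_problem(rng)
        model = fit_l1_logistic(H, y, lam=1e6)
        assert model.nonzero == 0

    def test_informative_kept_noise_dropped_at_moderate_lambda(self, rng):
        H, y = toy_problem(rng, n=500, strength=3.0)
        model = fit_l1_logistic(H, y, lam=10.0)
        assert model.coef[0] != 0.0
        assert np.count_nonzero(model.coef[1:]) == 0

    def test_objective_beats_grid_oracle(self, rng):
        """2-feature toy: the fitted objective value is at least as good as
        every point of a dense grid over the penalized objective."""
        H, y = toy_problem(rng, n=120, q=2, strength=3.0)
        lam = 5.0
        model = fit_l1_logistic(H, y, lam=lam)

        def objective(b0, b1, b2):
            eta = b0 + H[:, 0] * b1 + H[:, 1] * b2
            nll = np.logaddexp(0, -(2 * y - 1) * eta).sum()
            return nll + lam * (abs(b1) + abs(b2))

        fitted = objective(model.intercept, *model.coef)
        grid = np.linspace(-4, 4, 33)
        best_grid = min(
            objective(b0, b1, b2) for b0 in grid for b1 in grid for b2 in grid
        )
        assert fitted <= best_grid + 1e-6

    def test_lambda_zero_matches_statsmodels(self, rng):
        H, y = toy_problem(rng, n=400)
        model = fit_l1_logistic(H, y, lam=0.0)
        ref = sm.Logit(y, sm.add_constant(H)).fit(disp=0)
        assert model.intercept == pytest.approx(ref.params[0], abs=1e-4)
        assert np.allclose(model.coef, ref.params[1:], atol=1e-4)

    def test_agrees_with_sklearn_saga_at_positive_lambda(self, rng):
        H, y = toy_problem(rng, n=400)
        lam = 0.1
        model = fit_l1_logistic(H, y, lam=lam)
        clf = LogisticRegression(
            l1_ratio=1.0, C=1 / lam, solver="saga", tol=1e-8, max_iter=20000
        ).fit(H, y)
        assert np.allclose(model.coef, clf.coef_.ravel(), atol=2e-3)
        assert model.intercept == pytest.approx(clf.intercept_[0], abs=2e-3)

    def test_sparsity_trend_over_lambda_gap(self, rng):
        H, y = toy_problem(rng, n=200, q=30, strength=1.0)
        n_small = fit_l1_logistic(H, y, lam=1e-4).nonzero
        n_large = fit_l1_logistic(H, y, lam=1e-2).nonzero
        assert n_large <= n_small

    def test_single_class_rejected(self, rng):
        H = rng.random((10, 2))
        with pytest.raises(UndefinedTestError):
            fit_l1_logistic(H, np.ones(10), lam=0.1)


class TestPredict:
    def test_zero_model_scores_half(self):
        model = RiskModel(coef=np.zeros(3), intercept=0.0, lam=0.0)
        scores = predict_risk(model, np.random.default_rng(0).random((5, 3)))
        assert np.allclose(scores, 0.5)

    def test_intercept_shift_raises_every_score(self, rng):
        H = rng.random((6, 2))
        base = RiskModel(coef=np.array([1.0, -0.5]), intercept=0.0, lam=0.0)
        shifted = RiskModel(coef=base.coef, intercept=1.0, lam=0.0)
        assert (predict_risk(shifted, H) > predict_risk(base, H)).all()

    def test_closed_form_three_samples(self):
        model = RiskModel(coef=np.array([2.0]), intercept=-1.0, lam=0.0)
        H = np.array([[0.0], [0.5], [1.0]])
        expected = 1 / (1 + np.exp(-(H[:, 0] * 2.0 - 1.0)))
        assert np.allclose(predict_risk(model, H), expected)

    def test_column_mismatch_raises(self, rng):
        model = RiskModel(coef=np.ones(2), intercept=0.0, lam=0.0)
        with pytest.raises(AlignmentError):
            predict_risk(model, rng.random((4, 3)))


class TestAuc:
    def test_perfect_ranking(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_pairwise_enumeration(self, rng):
        for _ in range(100):
            scores = rng.random(8)
            labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
            rng.shuffle(labels)
            total = 0.0
            for i in np.flatnonzero(labels == 1):
                for j in np.flatnonzero(labels == 0):
                    if scores[i] > scores[j]:
                        total += 1.0
                    elif scores[i] == scores[j]:
                        total += 0.5
            assert auc(scores, labels) == pytest.approx(total / 16)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a = auc(scores, labels)
        assert auc(np.exp(5 * scores), labels) == pytest.approx(a)
        assert auc(scores**3 + 7, labels) == pytest.approx(a)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedTestError):
            auc([0.1, 0.9], [1, 1])


class TestUnivariateEffects:
    def test_matches_statsmodels_logit(self, rng):
        n = 200
        G = rng.binomial(2, 0.3, size=(5, n)).astype(float)
        eta = -0.5 + 0.8 * G[2]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        slopes = univariate_logistic_effects(G, y)
        for i in range(5):
            ref = sm.Logit(y, sm.add_constant(G[i])).fit(disp=0)
            assert slopes[i] == pytest.approx(ref.params[1], abs=1e-6)

    def test_constant_genotype_gets_zero_slope(self, rng):
        G = np.vstack([np.full(50, 1.0), rng.binomial(2, 0.4, 50)])
        y = np.array([1] * 25 + [0] * 25)
        slopes = univariate_logistic_effects(G, y)
        assert slopes[0] == 0.0


class TestPolygenicScore:
    def make_pair(self, counts_train, pheno_train, counts_test, pheno_test):
        train = make_dataset(counts_train, pheno_train)
        test = make_dataset(counts_test, pheno_test)
        return train, test

    def test_closed_form_single_locus(self, rng):
        # strong training association; gamma then applied to test genotypes
        counts = [[2] * 18 + [1, 0] + [0] * 20]
        train = make_dataset(counts, [1] * 20 + [0] * 20)
        test = make_dataset([[0, 1, 2]], [1, 0, 0])
        model, scores = polygenic_score(train, test, alpha=0.05)
        assert model.locus_ids == ["rs1"]
        gamma = model.gamma[0]
        assert gamma > 0
        assert np.allclose(scores, [0.0, gamma, 2 * gamma])

    def test_score_is_weighted_sum_over_selected_loci(self, rng):
        counts = rng.binomial(2, 0.4, size=(6, 80)).astype(np.int8)
        pheno = np.array([1] * 40 + [0] * 40)
        train = make_dataset(counts, pheno)
        test = make_dataset(
            rng.binomial(2, 0.4, size=(6, 10)).astype(np.int8), [1] * 5 + [0] * 5
        )
        model, scores = polygenic_score(train, test, alpha=0.9)
        sel = [test.locus_ids.index(lid) for lid in model.locus_ids]
        coded = np.where(
            train.minor_is_allele2[sel][:, None],
            test.genotypes[sel],
            2 - test.genotypes[sel],
        ).astype(float)
        assert np.allclose(scores, model.gamma @ coded)

    def test_empty_locus_set_raises(self):
        train = make_dataset([[1, 0, 1, 0]], [1, 1, 0, 0])
        test = make_dataset([[1, 0, 1, 0]], [1, 1, 0, 0])
        with pytest.raises(UndefinedTestError, match="alpha"):
            polygenic_score(train, test, alpha=1e-12)

    def test_planted_additive_cohort_scores_above_chance(self):
        spec = SimulationSpec(
            n_cases=300,
            n_controls=300,
            n_loci=60,
            modules=(
                PlantedModule(2, 0.3, "carrier", "union", 3.0),
                PlantedModule(2, 0.3, "carrier", "union", 3.0),
            ),
            base_odds=0.2,
            seed=7,
        )
        ds, _ = simulate_cohort(spec)
        half = ds.n_samples // 2
        train = ds.subset_samples(np.arange(half))
        test = ds.subset_samples(np.arange(half, ds.n_samples))
        _, scores = polygenic_score(train, test, alpha=0.05)
        assert auc(scores, test.phenotype) > 0.55


class TestNestedCV:
    def small_cohort(self):
        spec = SimulationSpec(
            n_cases=60,
            n_controls=60,
            n_loci=30,
            modules=(PlantedModule(2, 0.3, "carrier", "union", 3.0),),
            base_odds=0.3,
            seed=5,
        )
        ds, _ = simulate_cohort(spec)
        return ds

    def fast_cv(self):
        return CVConfig(n_folds=3, n_inner_folds=3, n_repeats=2, seed=1)

    def test_out_of_fold_scores_complete_and_valid(self):
        ds = self.small_cohort()
        res = nested_cv(ds, PipelineConfig(method="free"), self.fast_cv())
        assert res.oof_scores.shape == (2, ds.n_samples)
        assert np.isfinite(res.oof_scores).all()
        assert len(res.repeat_aucs) == 2
        assert all(0.0 <= a <= 1.0 for a in res.repeat_aucs)
        assert len(res.seeds) == 2

    def test_identical_seed_reproduces_result(self):
        ds = self.small_cohort()
        a = nested_cv(ds, PipelineConfig(method="loci"), self.fast_cv())
        b = nested_cv(ds, PipelineConfig(method="loci"), self.fast_cv())
        assert a.repeat_aucs == b.repeat_aucs
        assert np.array_equal(a.oof_scores, b.oof_scores)

    def test_training_stages_never_see_test_samples(self, monkeypatch):
        """Leakage guard: every model-selection call happens on a strict
        subset of the samples."""
        ds = self.small_cohort()
        seen = []
        original = rm.select_models

        def recording(ds_arg, *a, **k):
            seen.append(ds_arg.n_samples)
            return original(ds_arg, *a, **k)

        monkeypatch.setattr(rm, "select_models", recording)
        nested_cv(ds, PipelineConfig(method="free"), self.fast_cv())
        assert seen
        assert max(seen) < ds.n_samples

    def test_prs_pipeline_runs_and_reports_sizes(self):
        ds = self.small_cohort()
        res = nested_cv(ds, PipelineConfig(method="prs"), self.fast_cv())
        assert res.mean_model_size >= 0.0
        assert np.isfinite(res.mean_auc)
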