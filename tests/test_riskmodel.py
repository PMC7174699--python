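"""Logistic fitting, LOOCV reports, and the AUC primitive."""

import numpy as np
import pytest

from impactnet import (
    NodeImportance,
    RiskModelError,
    SeparationWarning,
    auc,
    epv_cap,
    evaluate_predictor_sets,
    fit_logistic,
    gen_atlas,
    gen_cohort,
    gen_impacts,
    loocv,
    per_subject_evaluation,
    rank_by_strain,
    sweep,
)
from impactnet.lesion import aggregate_importance

from .oracles import brute_auc


class TestEPVCap:
    def test_twenty_events_allow_four_predictors(self):
        assert epv_cap(20) == 4

    def test_too_few_events_rejected(self):
        with pytest.raises(RiskModelError):
            epv_cap(3)


class TestFitLogistic:
    def test_null_model_recovers_class_balance(self):
        rng = np.random.default_rng(0)
        y = (rng.random(400) < 0.3).astype(int)
        X = np.zeros((400, 1))
        model = fit_logistic(X, y, regularization=1.0)
        p = y.mean()
        assert model.coefficients[0] == pytest.approx(0.0, abs=1e-6)
        assert model.intercept == pytest.approx(np.log(p / (1 - p)), abs=0.05)

    def test_zero_variance_needs_regularization(self):
        y = np.array([0, 1, 0, 1])
        X = np.ones((4, 1))
        with pytest.raises(RiskModelError, match="zero-variance"):
            fit_logistic(X, y, regularization=0.0)

    def test_single_class_rejected(self):
        with pytest.raises(RiskModelError):
            fit_logistic(np.random.default_rng(0).normal(size=(5, 1)), np.ones(5))

    def test_separation_triggers_ridge_fallback(self):
        X = np.linspace(-1, 1, 20).reshape(-1, 1)
        y = (X.ravel() > 0).astype(int)
        with pytest.warns(SeparationWarning):
            model = fit_logistic(X, y, regularization=0.0)
        assert model.separation_fallback
        assert model.converged
        preds = model.predict_proba(X) >= 0.5
        assert np.array_equal(preds, y == 1)

    def test_parameter_recovery_shrinks_with_n(self):
        """MLE error on known coefficients is small at n=2000 and shrinks vs n=200."""
        beta = np.array([1.5, -0.7])

        def fit_err(n, seed):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(n, 2))
            p = 1 / (1 + np.exp(-(X @ beta)))
            y = (rng.random(n) < p).astype(int)
            return np.abs(fit_logistic(X, y).coefficients - beta).max()

        errs_small = [fit_err(200, s) for s in range(5)]
        errs_large = [fit_err(2000, s) for s in range(5)]
        assert np.mean(errs_large) < np.mean(errs_small)
        assert all(e < 0.15 for e in errs_large)

    def test_original_scale_coefficients(self):
        """Internal standardization is invisible in the reported scale."""
        rng = np.random.default_rng(3)
        X = rng.normal(loc=50.0, scale=9.0, size=(500, 1))
        beta = 0.2
        p = 1 / (1 + np.exp(-(X.ravel() * beta - 10.0)))
        y = (rng.random(500) < p).astype(int)
        model = fit_logistic(X, y)
        assert model.coefficients[0] == pytest.approx(beta, rel=0.3)
        manual = 1 / (1 + np.exp(-(X @ model.coefficients + model.intercept)))
        assert np.allclose(model.predict_proba(X), manual)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_worked_pair_counting_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(RiskModelError):
            auc([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, size=30).astype(float)  # forces ties
        y = (rng.random(30) < 0.4).astype(int)
        if len(set(y)) < 2:
            y[0] = 1 - y[0]
        assert auc(scores, y) == pytest.approx(brute_auc(scores, y), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        scores = rng.normal(size=50)
        y = (rng.random(50) < 0.4).astype(int)
        assert auc(scores, y) == pytest.approx(roc_auc_score(y, scores))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        assert auc(scores, y) == pytest.approx(auc(np.exp(scores), y))
        assert auc(scores, y) == pytest.approx(auc(3 * scores - 7, y))


class TestLOOCV:
    def test_confusion_identity(self):
        rng = np.random.default_rng(5)
        y = (rng.random(40) < 0.4).astype(int)
        X = (y + rng.normal(0, 1.0, 40)).reshape(-1, 1)
        rep = loocv(X, y)
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        assert rep.accuracy * 40 == pytest.approx(
            rep.sensitivity * n_pos + rep.specificity * n_neg
        )

    def test_perfectly_separable_predictor(self):
        y = np.array([0] * 10 + [1] * 10)
        X = np.concatenate([np.linspace(0, 1, 10), np.linspace(5, 6, 10)])
        rep = loocv(X.reshape(-1, 1), y)
        assert rep.accuracy == 1.0
        assert rep.auc_testing == 1.0

    def test_constant_predictor_is_majority_class(self):
        """With no signal at all, every fold predicts the training class rate."""
        y = np.array([1] * 20 + [0] * 33)
        X = np.ones((53, 1))
        rep = loocv(X, y, regularization=1e-6)
        assert rep.accuracy == pytest.approx(33 / 53)
        assert rep.sensitivity == 0.0
        assert rep.specificity == 1.0
        # pooled out-of-fold scores of a constant predictor are exactly the
        # training-fold prevalences, which anti-rank the held-out labels:
        # the pooled LOOCV ROC of a useless predictor collapses to 0, not 0.5
        assert rep.auc_testing == pytest.approx(0.0)

    def test_null_predictor_near_majority_rate(self):
        """Pure-noise predictors converge to majority-class accuracy.

        The pooled out-of-fold AUC of an uninformative predictor is
        systematically *below* 0.5 (each held-out case depresses its own
        score through the fold's prevalence and coefficients), so only its
        pessimistic direction is asserted here.
        """
        rng = np.random.default_rng(0)
        accs, aucs = [], []
        for _ in range(25):
            y = np.zeros(53, dtype=int)
            y[:20] = 1
            rng.shuffle(y)
            X = rng.normal(size=(53, 1))
            rep = loocv(X, y)
            accs.append(rep.accuracy)
            aucs.append(rep.auc_testing)
        assert np.mean(accs) == pytest.approx(33 / 53, abs=0.05)
        assert np.mean(aucs) < 0.5

    def test_duplicated_predictor_equals_single_with_ridge(self):
        rng = np.random.default_rng(9)
        y = (rng.random(40) < 0.4).astype(int)
        x = (y + rng.normal(0, 0.8, 40)).reshape(-1, 1)
        a = loocv(x, y, regularization=1e-3)
        b = loocv(np.hstack([x, x]), y, regularization=1e-3)
        assert a.accuracy == b.accuracy
        assert a.auc_testing == pytest.approx(b.auc_testing, abs=0.02)

    def test_needs_three_cases(self):
        with pytest.raises(RiskModelError):
            loocv(np.zeros((2, 1)), np.array([0, 1]))


@pytest.fixture(scope="module")
def dataset():
    atlas = gen_atlas(40, 4, 4, seed=1)
    cases = gen_impacts(atlas, 53, 20, seed=1)
    ranking = rank_by_strain(cases, atlas.region_ids)
    return atlas, cases, ranking


class TestEvaluatePredictorSets:
    def test_epv_cap_enforced(self, dataset):
        _, cases, ranking = dataset
        with pytest.raises(RiskModelError, match="events-per-variable"):
            evaluate_predictor_sets(cases, ranking, max_k=5)

    def test_report_set_structure(self, dataset):
        _, cases, ranking = dataset
        reports = evaluate_predictor_sets(cases, ranking, max_k=4)
        # 5 univariate baselines + k = 1..4 region sets
        assert len(reports) == 9
        sizes = [len(r.predictor_set) for r in reports[5:]]
        assert sizes == [1, 2, 3, 4]

    def test_beats_null_accuracy_on_effect_data(self, dataset):
        _, cases, ranking = dataset
        reports = evaluate_predictor_sets(cases, ranking, max_k=2)
        top1 = next(r for r in reports if r.predictor_set[0].startswith("rmps"))
        assert top1.accuracy > 33 / 53

    def test_same_top_k_set_order_invariant(self, dataset):
        """Region order within the top-k set does not change the report."""
        _, cases, ranking = dataset
        ids = ranking.region_ids
        # build a ranking with the same top-2 set in swapped order
        scores = np.array(ranking.scores)
        top2 = ranking.top(2)
        i, j = ids.index(top2[0]), ids.index(top2[1])
        scores[i], scores[j] = scores[j], scores[i]
        swapped = NodeImportance.from_scores(ids, scores, "swapped")
        a = evaluate_predictor_sets(cases, ranking, 2, include_baselines=False)[-1]
        b = evaluate_predictor_sets(cases, swapped, 2, include_baselines=False)[-1]
        assert a.accuracy == b.accuracy
        assert a.auc_testing == pytest.approx(b.auc_testing)


class TestPerSubjectEvaluation:
    def test_zero_noise_cohort_zero_spread(self):
        atlas = gen_atlas(25, 3, 3, seed=2)
        cohort = gen_cohort(atlas, 4, 0.0, seed=2)
        cases = gen_impacts(atlas, 30, 10, seed=2)
        rankings = [aggregate_importance(sweep(c, 1)) for c in cohort]
        summary = per_subject_evaluation(cases, rankings, k=2)
        assert summary.accuracy_min == summary.accuracy_max

    def test_noisy_cohort_ordering_sane(self):
        atlas = gen_atlas(25, 3, 3, seed=3)
        cohort = gen_cohort(atlas, 6, 0.5, seed=3)
        cases = gen_impacts(atlas, 30, 10, seed=3)
        rankings = [aggregate_importance(sweep(c, 1)) for c in cohort]
        summary = per_subject_evaluation(cases, rankings, k=2)
        assert summary.accuracy_min <= summary.accuracy_mean <= summary.accuracy_max
        assert len(summary.reports) == 6
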