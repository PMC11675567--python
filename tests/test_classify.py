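"""Classification tasks, splitting, metrics, tuning."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from voicecog.classify import (
    ModelSpec,
    SplitConfig,
    TaskCounts,
    average_precision,
    baseline_pr_auc,
    evaluate,
    make_tasks,
    rank_auc,
    stratified_split,
    task_data,
    tune_and_train,
    _build_pipeline,
    _fit,
)
from voicecog.cohort import Subject
from voicecog.synthesis import CohortSimulationParams, generate_cohort, generate_roster


def _roster(n_severe, n_mild, n_normal):
    return generate_roster((n_severe, n_mild, n_normal), seed=0)


class TestCountsAndBaseline:
    def test_counts_validation(self):
        with pytest.raises(ValueError):
            TaskCounts(n_positive=5, n_total=5)
        with pytest.raises(ValueError):
            TaskCounts(n_positive=0, n_total=5)

    @pytest.mark.parametrize(
        "n_pos, n_total, expected",
        [(72, 169, 0.426), (54, 151, 0.358), (151, 223, 0.677), (1, 2, 0.5)],
    )
    def test_baselines(self, n_pos, n_total, expected):
        value = baseline_pr_auc(TaskCounts(n_positive=n_pos, n_total=n_total))
        assert round(value, 3) == expected


class TestMakeTasks:
    def test_printed_cohort_counts(self):
        tasks = {t.name: t for t in make_tasks(_roster(72, 54, 97))}
        assert tasks["severe_vs_normal"].counts == TaskCounts(72, 169)
        assert tasks["mild_vs_normal"].counts == TaskCounts(54, 151)
        assert tasks["combined_vs_normal"].counts == TaskCounts(126, 223)

    def test_missing_group_skips_task(self):
        with pytest.warns(UserWarning, match="mild_vs_normal"):
            tasks = make_tasks(_roster(10, 0, 10))
        assert {t.name for t in tasks} == {"severe_vs_normal", "combined_vs_normal"}

    def test_task_data_labels(self):
        roster = _roster(5, 4, 6)
        params = CohortSimulationParams(group_sizes=(5, 4, 6), n_features=3, seed=0)
        table, roster = generate_cohort(params)
        task = {t.name: t for t in make_tasks(roster)}["mild_vs_normal"]
        X, y = task_data(task, table, roster)
        assert X.shape == (10, 3)
        assert y.sum() == 4


class TestStratifiedSplit:
    def test_proportions(self):
        labels = np.array([1] * 40 + [0] * 60)
        train, test = stratified_split(labels, SplitConfig(seed=0))
        assert test.size == 20
        assert labels[test].sum() == 8

    def test_determinism(self):
        labels = np.array([1] * 40 + [0] * 60)
        t1 = stratified_split(labels, SplitConfig(seed=5))
        t2 = stratified_split(labels, SplitConfig(seed=5))
        np.testing.assert_array_equal(t1[0], t2[0])
        np.testing.assert_array_equal(t1[1], t2[1])

    def test_223_sample_split_size(self):
        # 223 * 0.2 = 44.6; floor-plus-remainder rule gives 45
        labels = np.array([1] * 72 + [0] * 151)
        _, test = stratified_split(labels, SplitConfig(seed=1))
        assert test.size in (44, 45)
        assert test.size == 45
        assert labels[test].sum() == 15  # 14.4 floored + remainder

    def test_disjoint_and_complete(self):
        labels = np.array([0, 1] * 20)
        train, test = stratified_split(labels, SplitConfig(seed=2))
        assert set(train) | set(test) == set(range(40))
        assert set(train) & set(test) == set()

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([0, 0, 0, 1]), SplitConfig(seed=0))


class TestMetrics:
    def test_perfect_ranking(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        assert average_precision(labels, scores) == 1.0
        assert rank_auc(labels, scores) == 1.0

    def test_worked_average_precision(self):
        labels = np.array([1, 0, 1, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        assert average_precision(labels, scores) == pytest.approx((1 + 2 / 3) / 2)

    def test_constant_scorer_equals_prevalence(self):
        labels = np.array([1] * 3 + [0] * 7)
        scores = np.full(10, 0.5)
        assert average_precision(labels, scores) == pytest.approx(0.3)

    def test_agrees_with_sklearn_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(5, 60))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # force ties
            assert average_precision(labels, scores) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )
            assert rank_auc(labels, scores) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        scores = rng.random(40)
        transformed = np.exp(3 * scores) - 0.5
        assert average_precision(labels, scores) == pytest.approx(
            average_precision(labels, transformed)
        )
        assert rank_auc(labels, scores) == pytest.approx(rank_auc(labels, transformed))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            average_precision(np.ones(5), np.random.default_rng(0).random(5))


class TestEvaluate:
    @pytest.fixture(scope="class")
    def trained_on_separable(self):
        params = CohortSimulationParams(
            group_sizes=(30, 0, 40), n_features=12,
            effect_map={f"ind{i:03d}": {"severe": 1.5} for i in range(6)}, seed=7,
        )
        table, roster = generate_cohort(params)
        task = {t.name: t for t in make_tasks(roster)}["severe_vs_normal"]
        X, y = task_data(task, table, roster)
        train, test = stratified_split(y, SplitConfig(seed=7))
        model = tune_and_train(
            X.iloc[train], y[train],
            ModelSpec(family="linear_logistic", search_budget=2, seed=7),
            SplitConfig(seed=7),
        )
        return model, X.iloc[test], y[test], task.counts

    def test_report_fields(self, trained_on_separable):
        model, X_test, y_test, counts = trained_on_separable
        report = evaluate(model, X_test, y_test, counts)
        for value in (report.pr_auc, report.auc, report.accuracy, report.f1,
                      report.precision, report.recall):
            assert 0.0 <= value <= 1.0
        assert report.baseline_pr_auc == pytest.approx(30 / 70)
        assert report.improvement_pct == pytest.approx(
            (report.pr_auc - report.baseline_pr_auc) / report.baseline_pr_auc * 100
        )

    def test_improvement_pct_printed_pair(self):
        # printed PR-AUC 0.737 over the 72/169 baseline rounds to 73 %
        base = baseline_pr_auc(TaskCounts(72, 169))
        assert round((0.737 - base) / base * 100) == 73

    def test_single_class_test_set_rejected(self, trained_on_separable):
        model, X_test, y_test, counts = trained_on_separable
        with pytest.raises(ValueError):
            evaluate(model, X_test, np.zeros_like(y_test), counts)


class TestTuneAndTrain:
    def test_budget_one_returns_single_configuration(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        y = np.array([0, 1] * 20)
        model = tune_and_train(
            X, y, ModelSpec(family="linear_logistic", search_budget=1, seed=0),
            SplitConfig(seed=0),
        )
        assert len(model.cv_record) == 1
        assert model.best_params == model.cv_record[0]["params"]

    def test_determinism(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 6))
        y = rng.integers(0, 2, 50)
        y[:5], y[5:10] = 0, 1
        spec = ModelSpec(family="random_forest", search_budget=2, seed=3)
        m1 = tune_and_train(X, y, spec, SplitConfig(seed=3))
        m2 = tune_and_train(X, y, spec, SplitConfig(seed=3))
        assert m1.best_params == m2.best_params
        assert m1.best_cv_pr_auc == m2.best_cv_pr_auc
        np.testing.assert_array_equal(
            m1.pipeline.predict_proba(X), m2.pipeline.predict_proba(X)
        )

    @pytest.mark.parametrize("family", ["gradient_boosting", "feedforward_nn"])
    def test_other_families_train(self, family):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (25, 4)), rng.normal(1.5, 1, (25, 4))])
        y = np.array([0] * 25 + [1] * 25)
        model = tune_and_train(
            X, y, ModelSpec(family=family, search_budget=1, seed=1), SplitConfig(seed=1)
        )
        assert model.pipeline.predict_proba(X).shape == (50, 2)

    def test_fold_hygiene_imputer_ignores_test_rows(self):
        # leak detector: the held-out rows carry extreme values; statistics
        # fitted on the training rows must not see them
        rng = np.random.default_rng(4)
        X_train = rng.normal(0, 1, (30, 3))
        X_train[::4, 0] = np.nan
        X_test = np.full((10, 3), 1e6)
        y_train = np.array([0, 1] * 15)
        pipe = _build_pipeline("linear_logistic", {"C": 1.0}, seed=0)
        _fit(pipe, X_train, y_train)
        fitted_median = pipe.named_steps["impute"].statistics_[0]
        expected = np.nanmedian(X_train[:, 0])
        assert fitted_median == pytest.approx(expected)
        pipe.predict_proba(X_test)  # scoring test rows must not refit
        assert pipe.named_steps["impute"].statistics_[0] == pytest.approx(expected)

    def test_null_cohort_cv_near_prevalence(self):
        excess = []
        for seed in range(6):
            params = CohortSimulationParams(group_sizes=(80, 0, 120), n_features=50, seed=seed)
            table, roster = generate_cohort(params)
            task = {t.name: t for t in make_tasks(roster)}["severe_vs_normal"]
            X, y = task_data(task, table, roster)
            model = tune_and_train(
                X, y, ModelSpec(family="linear_logistic", search_budget=3, seed=seed),
                SplitConfig(seed=seed),
            )
            excess.append(model.best_cv_pr_auc - y.mean())
        assert np.mean(excess) < 0.1

    def test_effect_cohort_beats_prevalence(self):
        gaps = []
        for seed in range(4):
            params = CohortSimulationParams(
                group_sizes=(30, 0, 40), n_features=50,
                effect_map={f"ind{i:03d}": {"severe": 1.5} for i in range(10)},
                seed=seed,
            )
            table, roster = generate_cohort(params)
            task = {t.name: t for t in make_tasks(roster)}["severe_vs_normal"]
            X, y = task_data(task, table, roster)
            model = tune_and_train(
                X, y, ModelSpec(family="linear_logistic", search_budget=3, seed=seed),
                SplitConfig(seed=seed),
            )
            gaps.append(model.best_cv_pr_auc - y.mean())
        assert np.mean(gaps) >= 0.15
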