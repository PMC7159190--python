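"""Classification and ROC inference: splits, penalised fits, AUC identities,
thresholds, bootstrap bands and the rank test."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import kstest

from elemdyn.featurize import feature_columns
from elemdyn.prediction import (
    BoostedTreesClassifier,
    LassoClassifier,
    SplitSpec,
    auc_rank_test,
    bootstrap_roc,
    fit_gbt,
    fit_lasso,
    optimal_threshold,
    roc_and_auc,
    split_train_test,
    top_k_refit,
)


def make_table(rng, n_cases=36, n_controls=31, signal=1.5, n_noise=6):
    n = n_cases + n_controls
    case = np.array([1] * n_cases + [0] * n_controls)
    data = {
        "subject_id": [f"s{i}" for i in range(n)],
        "group": np.where(case == 1, "case", "control"),
        "sex": rng.integers(0, 2, n),
        "age": rng.normal(55, 10, n),
        "Cu_n_states": rng.normal(0, 1, n) + signal * case,
        "Cu_det": rng.normal(0, 1, n) + 0.5 * signal * case,
    }
    for i in range(n_noise):
        data[f"X{i}_det"] = rng.normal(0, 1, n)
    return pd.DataFrame(data)


class TestSplit:
    def test_sixty_forty_split_sizes(self, rng):
        table = make_table(rng)  # 67 rows
        for stratified in (True, False):
            train, test = split_train_test(
                table, SplitSpec(train_fraction=0.6, seed=3, stratified=stratified)
            )
            assert len(train) == 40 and len(test) == 27

    def test_stratified_balanced_toy(self, rng):
        table = make_table(rng, n_cases=2, n_controls=2)
        train, test = split_train_test(table, SplitSpec(0.5, seed=0, stratified=True))
        for part in (train, test):
            assert (part["group"] == "case").sum() == 1
            assert (part["group"] == "control").sum() == 1

    def test_single_class_rejected(self, rng):
        table = make_table(rng, n_cases=10, n_controls=1)
        table["group"] = "case"
        with pytest.raises(ValueError, match="single class"):
            split_train_test(table, SplitSpec())

    def test_deterministic_given_seed(self, rng):
        table = make_table(rng)
        a1, _ = split_train_test(table, SplitSpec(seed=7))
        a2, _ = split_train_test(table, SplitSpec(seed=7))
        pd.testing.assert_frame_equal(a1, a2)

    def test_feature_schema_excludes_label_and_covariates(self, rng):
        table = make_table(rng)
        cols = feature_columns(table)
        assert "group" not in cols and "sex" not in cols and "age" not in cols
        assert "Cu_n_states" in cols and "Cu_det" in cols


class TestLasso:
    def test_separating_feature_enters_path_first(self, rng):
        n = 60
        y = np.array([1] * 30 + [0] * 30)
        X = pd.DataFrame(rng.normal(0, 1, (n, 5)), columns=[f"f{i}" for i in range(5)])
        X["f0"] = y * 2.0 - 1.0 + rng.normal(0, 0.01, n)  # near-perfect separator
        first = None
        for C in np.logspace(-3, 1, 40):  # strong -> weak penalty
            model = LassoClassifier(C_override=C).fit(X, y)
            nz = np.flatnonzero(model.coef_)
            if nz.size:
                first = X.columns[nz[0]]
                break
        assert first == "f0"

    def test_heavy_penalty_gives_intercept_only(self, rng):
        y = np.array([1] * 20 + [0] * 20)
        X = pd.DataFrame(rng.normal(0, 1, (40, 6)))
        model = LassoClassifier(C_override=1e-3).fit(X, y)
        assert np.all(model.coef_ == 0.0)

    def test_unpenalised_limit_matches_logistic_mle(self, rng):
        # well-conditioned toy: moderate effects, n >> p
        n = 300
        X = rng.normal(0, 1, (n, 2))
        logits = 0.8 * X[:, 0] - 0.5 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        model = LassoClassifier(C_override=1e8).fit(pd.DataFrame(X), y)
        Xs = model.scaler_.transform(X)
        ref = sm.Logit(y, sm.add_constant(Xs)).fit(disp=0)
        np.testing.assert_allclose(model.coef_, ref.params[1:], atol=1e-4)
        assert model.intercept_ == pytest.approx(ref.params[0], abs=1e-4)


class TestGBT:
    def test_single_signal_feature_tops_importance(self, rng):
        table = make_table(rng, signal=2.5)
        table["Cu_det"] = rng.normal(0, 1, len(table))  # leave one signal column
        model = fit_gbt(table, seed=0)
        ranking = model.feature_ranking(model.feature_names_)
        assert ranking.iloc[0]["feature"] == "Cu_n_states"

    def test_pure_noise_near_chance_on_test_set(self, rng):
        table = make_table(rng, signal=0.0)
        train, test = split_train_test(table, SplitSpec(seed=1))
        model = fit_gbt(train, seed=1)
        cols = feature_columns(table)
        auc = roc_and_auc(model.decision_function(test[cols]), test["group"]).auc
        assert abs(auc - 0.5) < 0.25

    def test_fewer_samples_than_folds_rejected(self):
        X = np.zeros((4, 2))
        y = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="3-fold"):
            BoostedTreesClassifier(cv_folds=3).fit(X, y)


def _pairwise_auc(scores, labels):
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    return wins / (len(cases) * len(controls))


class TestRoc:
    def test_worked_example(self):
        auc = roc_and_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]).auc
        assert auc == pytest.approx(0.75)

    def test_perfect_and_chance(self, rng):
        assert roc_and_auc([1, 1, 0, 0], [1, 1, 0, 0]).auc == 1.0
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        assert abs(roc_and_auc(scores, labels).auc - 0.5) < 0.05

    def test_trapezoid_equals_mann_whitney(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 40))
            labels = np.concatenate([np.ones(n // 2 + 1), np.zeros(n - n // 2 - 1)]).astype(int)
            scores = np.round(rng.random(n), 2)  # force some ties
            got = roc_and_auc(scores, labels).auc
            assert got == pytest.approx(_pairwise_auc(scores, labels), abs=1e-12)


class TestOptimalThreshold:
    def test_perfect_classifier_gap_midpoint(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert optimal_threshold(scores, labels) == pytest.approx(0.5)

    def test_single_value_scores(self):
        assert optimal_threshold(np.full(4, 0.3), [1, 0, 1, 0]) == pytest.approx(0.3)

    def test_matches_exhaustive_search(self, rng):
        for _ in range(20):
            scores = rng.random(30)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            got = optimal_threshold(scores, labels)
            uniq = np.unique(scores)
            cands = (uniq[:-1] + uniq[1:]) / 2
            best = max(
                cands,
                key=lambda t: (
                    np.mean(scores[labels == 1] >= t) - np.mean(scores[labels == 0] >= t),
                    -t,
                ),
            )
            assert got == pytest.approx(best)


class TestRankTest:
    def test_perfect_separation_exact_p(self):
        scores = np.concatenate([np.arange(10) + 100, np.arange(10)])
        labels = np.array([1] * 10 + [0] * 10)
        p = auc_rank_test(scores, labels)
        assert p == pytest.approx(1 / math.comb(20, 10), rel=1e-9)
        assert p < 1e-4

    def test_identical_scores_null_midpoint(self):
        assert auc_rank_test(np.full(10, 1.0), [1] * 5 + [0] * 5) == 0.5

    def test_null_p_distribution_uniform(self, rng):
        ps = []
        for _ in range(300):
            scores = rng.normal(0, 1, 24)
            labels = np.array([1] * 12 + [0] * 12)
            ps.append(auc_rank_test(scores, labels))
        assert kstest(ps, "uniform").pvalue > 0.01


class TestBootstrap:
    def test_degenerate_scores_collapse_to_chance(self):
        roc = bootstrap_roc(np.full(20, 0.4), [1] * 10 + [0] * 10, n_boot=100, seed=0)
        assert roc.auc == 0.5 and roc.auc_ci == (0.5, 0.5)

    def test_perfect_separation_ci_is_one(self):
        scores = np.array([0.9] * 8 + [0.1] * 8)
        labels = np.array([1] * 8 + [0] * 8)
        roc = bootstrap_roc(scores, labels, n_boot=100, seed=0)
        assert roc.auc_ci == (1.0, 1.0)

    def test_ci_brackets_point_estimate_and_band_monotone(self, rng):
        scores = rng.normal(0, 1, 40) + np.array([1] * 20 + [0] * 20)
        labels = np.array([1] * 20 + [0] * 20)
        roc = bootstrap_roc(scores, labels, n_boot=400, seed=5)
        lo, hi = roc.auc_ci
        assert lo <= roc.auc <= hi
        assert (np.diff(roc.band["tpr_low"]) >= -1e-12).all()
        assert roc.accuracy_at_threshold >= 0.5
        assert roc.n_boot > 380  # almost no resample is single-class here


class TestTopK:
    def test_k_equal_to_all_features_reproduces_full_model(self, rng):
        table = make_table(rng)
        train, test = split_train_test(table, SplitSpec(seed=2))
        cols = feature_columns(table)
        model = fit_lasso(train, seed=2)
        full_auc = roc_and_auc(model.decision_function(test[cols]), test["group"]).auc
        refit = top_k_refit(model, train, test, k=len(cols))
        assert refit.auc == pytest.approx(full_auc, abs=1e-12)

    def test_k_exceeding_features_rejected(self, rng):
        table = make_table(rng)
        train, test = split_train_test(table, SplitSpec(seed=2))
        model = fit_lasso(train, seed=2)
        with pytest.raises(ValueError, match="exceeds"):
            top_k_refit(model, train, test, k=100)

    def test_single_signal_survives_top_one_refit(self, rng):
        table = make_table(rng, signal=3.0)
        train, test = split_train_test(table, SplitSpec(seed=4))
        cols = feature_columns(table)
        model = fit_lasso(train, seed=4)
        full_auc = roc_and_auc(model.decision_function(test[cols]), test["group"]).auc
        refit = top_k_refit(model, train, test, k=1)
        assert refit.auc >= full_auc - 0.1
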