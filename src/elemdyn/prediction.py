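"""Disease classification from dynamical features, with ROC uncertainty.

Two classifier families mirror the comparative design: an L1-penalised
logistic model (LASSO; penalty chosen by cross-validated deviance on the
training split) and gradient-boosted trees tuned by 3-fold cross-validation
over a small grid.  Models are trained on a stratified 60/40 split and
evaluated on the untouched test split; test-set ROC uncertainty comes from
2000 bootstrap resamples of the (score, label) pairs, the decision threshold
maximises the distance from the chance diagonal (TPR - FPR), and
significance against chance uses the rank-based equivalence of the AUC with
the Mann-Whitney statistic.

Only dynamical features (state counts, DET, MDL, ENT per element) ever enter
the design matrix; the label and covariates are excluded by schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .featurize import feature_columns

__all__ = [
    "SplitSpec",
    "RocSummary",
    "split_train_test",
    "LassoClassifier",
    "BoostedTreesClassifier",
    "fit_lasso",
    "fit_gbt",
    "roc_and_auc",
    "optimal_threshold",
    "bootstrap_roc",
    "auc_rank_test",
    "top_k_refit",
    "evaluate_classifiers",
]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.6
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class RocSummary:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_ci: tuple | None = None
    band: dict | None = None  # {"fpr_grid", "tpr_low", "tpr_high"}
    optimal_threshold: float | None = None
    accuracy_at_threshold: float | None = None
    p_vs_chance: float | None = None
    n_boot: int = 0
    extras: dict = field(default_factory=dict)


def _labels01(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype.kind in "OUS":
        return (lab == "case").astype(int)
    return lab.astype(int)


def split_train_test(table: pd.DataFrame, spec: SplitSpec = SplitSpec()):
    """Deterministic train/test partition of the feature table.

    The training set gets floor(train_fraction * n) rows.  Under
    stratification, per-class sizes are allocated by largest remainder so
    the total still matches the floor rule.  Both partitions must contain
    both classes.
    """
    y = _labels01(table["group"])
    if len(np.unique(y)) < 2:
        raise ValueError("table contains a single class; cannot split")
    rng = np.random.default_rng(spec.seed)
    n_train = int(np.floor(spec.train_fraction * len(table)))

    if spec.stratified:
        idx_train: list[int] = []
        class_idx = {c: np.flatnonzero(y == c) for c in (1, 0)}
        quota = {c: spec.train_fraction * len(ix) for c, ix in class_idx.items()}
        take = {c: int(np.floor(q)) for c, q in quota.items()}
        leftover = n_train - sum(take.values())
        # distribute the remainder to the largest fractional parts (ties:
        # larger class first, then cases before controls)
        order = sorted(
            class_idx,
            key=lambda c: (quota[c] - take[c], len(class_idx[c]), c),
            reverse=True,
        )
        for c in order[:leftover]:
            take[c] += 1
        for c, ix in class_idx.items():
            perm = rng.permutation(ix)
            idx_train.extend(perm[: take[c]].tolist())
        train_mask = np.zeros(len(table), dtype=bool)
        train_mask[idx_train] = True
    else:
        perm = rng.permutation(len(table))
        train_mask = np.zeros(len(table), dtype=bool)
        train_mask[perm[:n_train]] = True

    train = table.iloc[np.flatnonzero(train_mask)].reset_index(drop=True)
    test = table.iloc[np.flatnonzero(~train_mask)].reset_index(drop=True)
    for part, name in ((train, "train"), (test, "test")):
        if len(part) == 0 or _labels01(part["group"]).std() == 0:
            raise ValueError(f"{name} partition is empty or single-class")
    return train, test


# --------------------------------------------------------------------------
# Classifiers
# --------------------------------------------------------------------------

class LassoClassifier(BaseEstimator, ClassifierMixin):
    """L1-penalised logistic classifier with internal standardisation.

    The penalty is selected by ``cv``-fold cross-validated deviance on the
    training data over a logarithmic grid of ``n_cs`` strengths.  Passing
    ``C_override`` skips selection (large values approximate the
    unpenalised logistic fit).  Fitted coefficients (standardised scale)
    are exposed in ``coef_``; zeros mean the feature was excluded, and
    ``feature_ranking`` orders features by |coefficient|.
    """

    def __init__(self, cv: int = 5, n_cs: int = 25, seed: int = 0,
                 C_override: float | None = None):
        self.cv = cv
        self.n_cs = n_cs
        self.seed = seed
        self.C_override = C_override

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = _labels01(y)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        if self.C_override is not None:
            model = LogisticRegression(
                penalty="l1", C=self.C_override, solver="liblinear",
                max_iter=5000,
            ).fit(Xs, y)
            self.C_ = float(self.C_override)
        else:
            # never ask for more folds than the minority class can populate
            n_min = int(np.bincount(y).min())
            if n_min < 2:
                raise ValueError("need at least 2 samples per class to cross-validate")
            folds = StratifiedKFold(min(self.cv, n_min), shuffle=True,
                                    random_state=self.seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                warnings.simplefilter("ignore", UserWarning)
                model = LogisticRegressionCV(
                    penalty="l1", solver="liblinear",
                    Cs=np.logspace(-2.5, 2.5, self.n_cs),
                    cv=folds, scoring="neg_log_loss", max_iter=5000,
                    refit=True,
                ).fit(Xs, y)
            self.C_ = float(model.C_[0])
        self.model_ = model
        self.coef_ = model.coef_.ravel()
        self.intercept_ = float(model.intercept_[0])
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        return self.model_.decision_function(self.scaler_.transform(np.asarray(X, float)))

    def predict_proba(self, X):
        return self.model_.predict_proba(self.scaler_.transform(np.asarray(X, float)))

    def predict(self, X):
        return self.model_.predict(self.scaler_.transform(np.asarray(X, float)))

    def feature_ranking(self, names) -> pd.DataFrame:
        df = pd.DataFrame({"feature": list(names), "coef": self.coef_})
        df["abs"] = df["coef"].abs()
        return df.sort_values("abs", ascending=False).drop(columns="abs").reset_index(drop=True)


class BoostedTreesClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted classification trees tuned by k-fold CV over a small
    declared grid (depth, number of trees, learning rate)."""

    GRID = {
        "max_depth": [2, 3],
        "n_estimators": [50, 150],
        "learning_rate": [0.1, 0.3],
    }

    def __init__(self, cv_folds: int = 3, seed: int = 0):
        self.cv_folds = cv_folds
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = _labels01(y)
        if len(y) < self.cv_folds or min(np.bincount(y)) < self.cv_folds:
            raise ValueError(
                f"need at least {self.cv_folds} samples per class for "
                f"{self.cv_folds}-fold cross-validation"
            )
        base = XGBClassifier(
            objective="binary:logistic", eval_metric="logloss",
            tree_method="hist", random_state=self.seed, n_jobs=1,
            verbosity=0,
        )
        folds = StratifiedKFold(self.cv_folds, shuffle=True, random_state=self.seed)
        search = GridSearchCV(base, self.GRID, cv=folds, scoring="roc_auc", n_jobs=1)
        search.fit(X, y)
        self.model_ = search.best_estimator_
        self.best_params_ = search.best_params_
        self.feature_importances_ = self.model_.feature_importances_
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))

    def feature_ranking(self, names) -> pd.DataFrame:
        df = pd.DataFrame(
            {"feature": list(names), "importance": self.feature_importances_}
        )
        return df.sort_values("importance", ascending=False).reset_index(drop=True)


def fit_lasso(train: pd.DataFrame, cv: int = 5, seed: int = 0,
              C_override: float | None = None) -> LassoClassifier:
    cols = feature_columns(train)
    model = LassoClassifier(cv=cv, seed=seed, C_override=C_override)
    model.fit(train[cols], train["group"])
    model.feature_names_ = cols
    return model


def fit_gbt(train: pd.DataFrame, cv_folds: int = 3, seed: int = 0) -> BoostedTreesClassifier:
    cols = feature_columns(train)
    model = BoostedTreesClassifier(cv_folds=cv_folds, seed=seed)
    model.fit(train[cols], train["group"])
    model.feature_names_ = cols
    return model


# --------------------------------------------------------------------------
# ROC machinery
# --------------------------------------------------------------------------

def roc_and_auc(scores, labels) -> RocSummary:
    """Empirical ROC by threshold sweep; trapezoid AUC (equals the
    Mann-Whitney pair statistic)."""
    y = _labels01(labels)
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) == 0:
        # degenerate scores: chance performance by convention
        return RocSummary(fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]), auc=0.5)
    fpr, tpr, _ = roc_curve(y, scores)
    return RocSummary(fpr=fpr, tpr=tpr, auc=float(roc_auc_score(y, scores)))


def optimal_threshold(scores, labels) -> float:
    """Threshold maximising TPR - FPR (max distance from the diagonal).

    Candidates are midpoints between adjacent distinct scores; ties go to
    the lower threshold, so a perfect classifier yields the midpoint of the
    separating gap.
    """
    y = _labels01(labels)
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(scores)
    if uniq.size == 1:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    best_t, best_j = None, -np.inf
    for t in candidates:
        pred = scores >= t
        tpr = np.sum(pred & (y == 1)) / n_pos
        fpr = np.sum(pred & (y == 0)) / n_neg
        j = tpr - fpr
        if j > best_j:  # first (lowest) threshold wins ties
            best_j, best_t = j, t
    return float(best_t)


def auc_rank_test(scores, labels) -> float:
    """One-sided test that the AUC exceeds 0.5, via the Mann-Whitney
    rank-sum equivalence.  Exact when sample sizes permit and there are no
    ties; otherwise the normal approximation with tie correction.  Fully
    tied scores return p = 0.5 (the null midpoint)."""
    y = _labels01(labels)
    scores = np.asarray(scores, dtype=float)
    cases = scores[y == 1]
    controls = scores[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("need scores for both classes")
    if np.ptp(scores) == 0:
        return 0.5
    has_ties = np.unique(scores).size < scores.size
    method = "exact" if (not has_ties and len(cases) * len(controls) <= 400) else "asymptotic"
    return float(mannwhitneyu(cases, controls, alternative="greater", method=method).pvalue)


def bootstrap_roc(scores, labels, n_boot: int = 2000, seed: int = 0,
                  fpr_grid: np.ndarray | None = None) -> RocSummary:
    """Point ROC plus percentile CIs from resampling (score, label) pairs.

    Each of ``n_boot`` resamples draws len(scores) pairs with replacement;
    resamples missing a class are skipped.  The AUC CI is the 2.5/97.5
    percentile; the sensitivity band interpolates each resample's ROC on a
    fixed specificity (FPR) grid.
    """
    y = _labels01(labels)
    scores = np.asarray(scores, dtype=float)
    summary = roc_and_auc(scores, y)
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    rng = np.random.default_rng(seed)
    n = len(scores)
    aucs, curves = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        sb = scores[idx]
        if np.ptp(sb) == 0:
            aucs.append(0.5)
            curves.append(fpr_grid.copy())
            continue
        fpr, tpr, _ = roc_curve(yb, sb)
        aucs.append(roc_auc_score(yb, sb))
        curves.append(np.interp(fpr_grid, fpr, tpr))
    aucs_arr = np.asarray(aucs)
    curves_arr = np.asarray(curves)
    summary.auc_ci = (
        float(np.percentile(aucs_arr, 2.5)),
        float(np.percentile(aucs_arr, 97.5)),
    )
    summary.band = {
        "fpr_grid": fpr_grid,
        "tpr_low": np.percentile(curves_arr, 2.5, axis=0),
        "tpr_high": np.percentile(curves_arr, 97.5, axis=0),
    }
    summary.n_boot = len(aucs)
    thr = optimal_threshold(scores, y)
    summary.optimal_threshold = thr
    summary.accuracy_at_threshold = float(np.mean((scores >= thr).astype(int) == y))
    summary.p_vs_chance = auc_rank_test(scores, y)
    return summary


def top_k_refit(model, train: pd.DataFrame, test: pd.DataFrame, k: int = 5,
                n_boot: int = 0, seed: int = 0) -> RocSummary:
    """Re-fit the same classifier family on the k most influential features
    (largest |coefficient| for the LASSO, highest importance for the trees)
    and evaluate on the untouched test split."""
    cols = model.feature_names_
    if k > len(cols):
        raise ValueError(f"k={k} exceeds the {len(cols)} available features")
    ranking = model.feature_ranking(cols)
    top = ranking["feature"].head(k).tolist()
    refit = clone(model)
    refit.fit(train[top], train["group"])
    scores = refit.decision_function(test[top])
    if n_boot:
        summary = bootstrap_roc(scores, test["group"], n_boot=n_boot, seed=seed)
    else:
        summary = roc_and_auc(scores, test["group"])
    summary.extras["features"] = top
    return summary


def evaluate_classifiers(
    table: pd.DataFrame,
    split: SplitSpec = SplitSpec(),
    classifiers=("lasso", "gbt"),
    n_boot: int = 2000,
    top_k: int = 5,
    seed: int = 0,
) -> dict:
    """Full predictive workflow on a feature table; returns one summary per
    classifier family plus its top-k refit."""
    train, test = split_train_test(table, split)
    cols = feature_columns(table)
    out: dict = {"n_train": len(train), "n_test": len(test), "features": cols}
    for name in classifiers:
        if name == "lasso":
            model = fit_lasso(train, seed=seed)
        elif name == "gbt":
            model = fit_gbt(train, seed=seed)
        else:
            raise ValueError(f"unknown classifier {name!r}")
        scores = model.decision_function(test[cols])
        summary = bootstrap_roc(scores, test["group"], n_boot=n_boot, seed=seed)
        entry = {
            "model": model,
            "roc": summary,
            "ranking": model.feature_ranking(cols),
        }
        if top_k and top_k <= len(cols):
            entry["top_k"] = top_k_refit(model, train, test, k=top_k,
                                         n_boot=n_boot, seed=seed)
        out[name] = entry
    return out
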