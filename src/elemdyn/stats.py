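"""Group-level hypothesis tests on the per-subject dynamical features.

State counts are compared between groups with Poisson regression (log link,
maximum likelihood) adjusted for sex and age; RQA features with ordinary
linear models under the same adjustment.  Tobacco history enters both models
when the column is present.  Raw p-values are reported alongside
Benjamini-Hochberg FDR-adjusted ones; adjustment is applied within each
feature family across elements (five tests per family) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .featurize import FEATURES

__all__ = [
    "TestResult",
    "fit_state_count_model",
    "fit_rqa_feature_model",
    "fdr_adjust",
    "compare_groups",
]


@dataclass
class TestResult:
    element: str
    feature: str
    estimate: float  # group (case vs control) coefficient on the link scale
    se: float
    p_raw: float
    p_fdr: float | None = None
    n_used: int = 0
    converged: bool = True
    note: str = ""


def _design(table: pd.DataFrame, outcome_col: str):
    """Response vector and design matrix [1, group, sex, age(, smoking)],
    complete cases only."""
    cols = [outcome_col, "group", "sex", "age"]
    if "smoking" in table.columns:
        cols.append("smoking")
    df = table[cols].dropna()
    if df["group"].nunique() != 2:
        raise ValueError("need exactly two groups (case/control)")
    y = df[outcome_col].to_numpy(dtype=float)
    group = (df["group"] == "case").astype(float).to_numpy()
    X = [np.ones(len(df)), group, df["sex"].to_numpy(dtype=float),
         df["age"].to_numpy(dtype=float)]
    if "smoking" in df.columns:
        X.append(df["smoking"].to_numpy(dtype=float))
    return y, np.column_stack(X), len(df)


def _degenerate(element: str, feature: str, n: int, note: str) -> TestResult:
    return TestResult(
        element=element, feature=feature, estimate=0.0, se=float("nan"),
        p_raw=1.0, n_used=n, converged=False, note=note,
    )


def fit_state_count_model(table: pd.DataFrame, element: str) -> TestResult:
    """Poisson regression of the state count on group + sex + age."""
    y, X, n = _design(table, f"{element}_n_states")
    if np.ptp(y) == 0:
        return _degenerate(element, "n_states", n, "constant outcome")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        converged = bool(fit.converged)
    except Exception as exc:  # separation / non-convergence stay non-fatal
        return _degenerate(element, "n_states", n, f"fit failed: {exc}")
    return TestResult(
        element=element, feature="n_states",
        estimate=float(fit.params[1]), se=float(fit.bse[1]),
        p_raw=float(fit.pvalues[1]), n_used=n, converged=converged,
    )


def fit_rqa_feature_model(table: pd.DataFrame, element: str, feature: str) -> TestResult:
    """OLS of an RQA feature on group + sex + age."""
    y, X, n = _design(table, f"{element}_{feature}")
    if np.ptp(y) == 0:
        return _degenerate(element, feature, n, "constant outcome")
    fit = sm.OLS(y, X).fit()
    return TestResult(
        element=element, feature=feature,
        estimate=float(fit.params[1]), se=float(fit.bse[1]),
        p_raw=float(fit.pvalues[1]), n_used=n,
    )


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up; NaN entries are passed through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def compare_groups(
    table: pd.DataFrame,
    elements=None,
    fdr_scope: str = "family",
) -> pd.DataFrame:
    """All state-count and RQA-feature tests with FDR adjustment.

    ``fdr_scope="family"`` adjusts within each feature family across
    elements; ``"pooled"`` adjusts over all tests jointly.
    """
    if elements is None:
        elements = sorted(
            {c.rsplit("_", 2)[0] for c in table.columns if c.endswith("_n_states")}
        )
    results: list[TestResult] = []
    for el in elements:
        results.append(fit_state_count_model(table, el))
        for feat in FEATURES[1:]:
            results.append(fit_rqa_feature_model(table, el, feat))
    df = pd.DataFrame(
        {
            "element": [r.element for r in results],
            "feature": [r.feature for r in results],
            "estimate": [r.estimate for r in results],
            "se": [r.se for r in results],
            "p_raw": [r.p_raw for r in results],
            "n_used": [r.n_used for r in results],
            "converged": [r.converged for r in results],
            "note": [r.note for r in results],
        }
    )
    if fdr_scope == "pooled":
        df["p_fdr"] = fdr_adjust(df["p_raw"])
    elif fdr_scope == "family":
        df["p_fdr"] = np.nan
        for feat in df["feature"].unique():
            mask = df["feature"] == feat
            df.loc[mask, "p_fdr"] = fdr_adjust(df.loc[mask, "p_raw"])
    else:
        raise ValueError("fdr_scope must be 'family' or 'pooled'")
    return df
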