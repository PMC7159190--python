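"""Repeatable validation studies exercising the whole pipeline.

Each function regenerates its inputs from a seed, runs the relevant stages
and returns measured quantities (recovery rates, rejection rates, AUCs).
They are used by the acceptance harness and are convenient for sanity checks
after any methodological change.  Study sizes (series lengths, numbers of
cohorts) are the package's own calibration choices and are stated in the
methods note.
"""

from __future__ import annotations

import warnings

import numpy as np

from .embedding import EmbeddingParams, estimate_delay, takens_embed
from .featurize import build_feature_table, feature_columns
from .potential import find_states, potential_from_density
from .prediction import (
    SplitSpec,
    auc_rank_test,
    fit_gbt,
    fit_lasso,
    roc_and_auc,
    split_train_test,
)
from .rqa import (
    RQAConfig,
    adaptive_epsilon,
    determinism,
    diagonal_entropy,
    mean_diagonal_length,
    recurrence_matrix,
    rqa_features,
)
from .series import BiomarkerSeries
from .stats import fit_rqa_feature_model, fit_state_count_model
from .synthetic import GENERATORS, null_cohort_spec, planted_cohort_spec, simulate_cohort

__all__ = [
    "adaptive_rate_benchmark",
    "rqa_worked_examples",
    "potential_closed_forms",
    "state_recovery",
    "periodicity_benchmark",
    "null_calibration",
    "planted_discrimination",
]


def _child_seeds(seed: int, count: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31, size=count)


def adaptive_rate_benchmark(seed: int = 0, n: int = 500) -> float:
    """Realised recurrence rate at the adaptive threshold on Gaussian noise
    embedded at m = 3, tau = 1 (target 10%)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    traj = takens_embed(z, EmbeddingParams(delay=1, dimension=3))
    cfg = RQAConfig()
    eps = adaptive_epsilon(traj, cfg)
    return recurrence_matrix(traj, eps, cfg).recurrence_rate


def rqa_worked_examples() -> dict:
    """Hand-checkable feature values from small diagonal-line histograms."""
    return {
        "determinism": determinism({1: 4, 3: 2}, lmin=3),  # 6/10
        "mdl": mean_diagonal_length({3: 2, 5: 1}, lmin=3),  # 11/3
        "entropy_two_classes": diagonal_entropy({3: 1, 4: 1}, lmin=3),  # ln 2
        "entropy_single_class": diagonal_entropy({5: 7}, lmin=3),  # 0
    }


def potential_closed_forms(grid_size: int = 500) -> dict:
    """Potential transform checked against closed-form densities.

    A standard-normal density must give an exactly quadratic potential
    (checked by the R^2 of a quadratic fit on the interior grid), and an
    equal-weight Gaussian mixture at +-1.5 (SD 0.3) must give two states
    with one tipping point near 0.
    """
    grid = np.linspace(-3.5, 3.5, grid_size)
    phi = np.exp(-0.5 * grid**2) / np.sqrt(2 * np.pi)
    u = potential_from_density(phi)
    interior = np.abs(grid) <= 3.0
    coef = np.polyfit(grid[interior], u[interior], 2)
    resid = u[interior] - np.polyval(coef, grid[interior])
    r2 = 1.0 - np.sum(resid**2) / np.sum((u[interior] - u[interior].mean()) ** 2)

    mix = 0.5 * np.exp(-0.5 * ((grid + 1.5) / 0.3) ** 2) + 0.5 * np.exp(
        -0.5 * ((grid - 1.5) / 0.3) ** 2
    )
    mix /= 0.3 * np.sqrt(2 * np.pi)
    u_mix = potential_from_density(mix)
    minima, maxima, n_states = find_states(grid, u_mix, mix)
    step = grid[1] - grid[0]
    return {
        "quadratic_r2": float(r2),
        "bimodal_n_states": n_states,
        "bimodal_minima": minima,
        "bimodal_maxima": maxima,
        "grid_step": float(step),
    }


def state_recovery(kind: str, n_seeds: int = 100, n: int = 500, seed: int = 0) -> float:
    """Fraction of simulated series whose landscape recovers the true state
    count (2 for the default double well, 1 for the OU well)."""
    from .potential import count_states

    gen, expected = {
        "double_well": ("bistable_well", 2),
        "ou": ("monostable_well", 1),
    }[kind]
    hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for s in _child_seeds(seed, n_seeds):
            series = GENERATORS[gen](n, int(s), 0.021)
            hits += count_states(series) == expected
    return hits / n_seeds


def periodicity_benchmark(seed: int = 0, n: int = 400, samples_per_period: int = 40) -> dict:
    """Delay recovery and determinism contrast: noiseless sinusoid vs white
    noise under the identical embedding and RQA configuration."""
    t = np.arange(n)
    sin_series = BiomarkerSeries(t * 0.02, np.sin(2 * np.pi * t / samples_per_period))
    delay = estimate_delay(sin_series, max_lag=30)
    res_sin = rqa_features(sin_series)
    rng = np.random.default_rng(seed)
    noise_series = BiomarkerSeries(t * 0.02, rng.standard_normal(n))
    res_noise = rqa_features(noise_series, params=res_sin.params)
    return {
        "delay": delay,
        "quarter_period": samples_per_period // 4,
        "determinism_sinusoid": res_sin.determinism,
        "determinism_noise": res_noise.determinism,
        "params": res_sin.params,
    }


#: reduced per-cohort settings for the repeated null-calibration study
_CALIB_KWARGS = dict(elements=["Cu"], length_range=(250, 250))
_CALIB_EMBED = {"max_lag": 25, "max_dim": 4}


def null_calibration(n_cohorts: int = 200, seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I behaviour of the three inferential routes on null cohorts.

    Each cohort (36 cases / 31 controls, identical bistable generators in
    both groups, single element) is run through feature extraction; the
    Poisson state-count test, the OLS determinism test and the classifier
    AUC rank test are applied, and their rejection rates at ``alpha`` are
    returned together with the mean test AUC (chance is 0.5).
    """
    seeds = _child_seeds(seed, n_cohorts)
    p_pois, p_ols, p_auc, aucs = [], [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in seeds:
            spec = null_cohort_spec(seed=int(s), **_CALIB_KWARGS)
            table = build_feature_table(
                simulate_cohort(spec), embedding_kwargs=_CALIB_EMBED
            )
            p_pois.append(fit_state_count_model(table, "Cu").p_raw)
            p_ols.append(fit_rqa_feature_model(table, "Cu", "det").p_raw)
            train, test = split_train_test(table, SplitSpec(seed=int(s)))
            cols = feature_columns(table)
            model = fit_lasso(train, seed=int(s))
            scores = model.decision_function(test[cols])
            p_auc.append(auc_rank_test(scores, test["group"]))
            aucs.append(roc_and_auc(scores, test["group"]).auc)
    return {
        "poisson_rejection": float(np.mean(np.asarray(p_pois) < alpha)),
        "ols_rejection": float(np.mean(np.asarray(p_ols) < alpha)),
        "auc_rank_rejection": float(np.mean(np.asarray(p_auc) < alpha)),
        "mean_null_auc": float(np.mean(aucs)),
        "n_cohorts": n_cohorts,
    }


def planted_discrimination(n_seeds: int = 25, seed: int = 0) -> dict:
    """Test-set discrimination of both classifier families on planted-effect
    cohorts (mono-stable copper in cases plus a determinism shift)."""
    seeds = _child_seeds(seed, n_seeds)
    auc_lasso, auc_gbt, p_lasso, p_gbt = [], [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in seeds:
            table = build_feature_table(
                simulate_cohort(planted_cohort_spec(seed=int(s)))
            )
            train, test = split_train_test(table, SplitSpec(seed=int(s)))
            cols = feature_columns(table)
            for fit, aucs, ps in (
                (fit_lasso, auc_lasso, p_lasso),
                (fit_gbt, auc_gbt, p_gbt),
            ):
                model = fit(train, seed=int(s))
                scores = model.decision_function(test[cols])
                aucs.append(roc_and_auc(scores, test["group"]).auc)
                ps.append(auc_rank_test(scores, test["group"]))
    return {
        "median_auc_lasso": float(np.median(auc_lasso)),
        "median_auc_gbt": float(np.median(auc_gbt)),
        "median_p_lasso": float(np.median(p_lasso)),
        "median_p_gbt": float(np.median(p_gbt)),
        "n_seeds": n_seeds,
    }
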