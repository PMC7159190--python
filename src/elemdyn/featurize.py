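"""Turn cohorts of series into the subjects x dynamical-features table.

For each subject and element the pipeline extracts four features: the number
of quasi-stable states from the potential landscape, and determinism, mean
diagonal length and diagonal entropy from RQA.  Degenerate series (constant
values, too short to embed) yield missing values, never exceptions -- the
downstream models drop them casewise.

``DynamicsFeaturizer`` exposes the same extraction as a scikit-learn
transformer so it composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import potential as pot
from .rqa import RQAConfig, rqa_features
from .series import BiomarkerSeries, Subject

__all__ = ["FEATURES", "extract_series_features", "build_feature_table",
           "feature_columns", "DynamicsFeaturizer"]

FEATURES = ("n_states", "det", "mdl", "ent")
#: per-element diagnostic columns kept in the table but never used as predictors
DIAGNOSTICS = ("tau", "m", "epsilon")


def extract_series_features(
    series: BiomarkerSeries,
    rqa_config: RQAConfig = RQAConfig(),
    embedding_kwargs: dict | None = None,
    grid_size: int = pot.GRID_SIZE,
    floor_fraction: float = pot.FLOOR_FRACTION,
) -> dict:
    """All four dynamical features (plus diagnostics) for one series."""
    out = {k: np.nan for k in FEATURES + DIAGNOSTICS}
    try:
        out["n_states"] = pot.count_states(
            series, grid_size=grid_size, floor_fraction=floor_fraction
        )
    except ValueError:
        pass
    try:
        res = rqa_features(series, config=rqa_config, **(embedding_kwargs or {}))
    except ValueError:
        return out
    out["det"] = res.determinism
    out["mdl"] = res.mean_diagonal_length
    out["ent"] = res.entropy
    out["tau"] = res.params.delay
    out["m"] = res.params.dimension
    out["epsilon"] = res.epsilon
    return out


def build_feature_table(
    subjects: list[Subject],
    rqa_config: RQAConfig = RQAConfig(),
    embedding_kwargs: dict | None = None,
    grid_size: int = pot.GRID_SIZE,
    floor_fraction: float = pot.FLOOR_FRACTION,
) -> pd.DataFrame:
    """One row per subject: label, covariates, then element x feature columns."""
    rows = []
    for subj in subjects:
        row: dict = {"subject_id": subj.subject_id, "group": subj.group}
        row.update(subj.covariates)
        for el, series in subj.series.items():
            feats = extract_series_features(
                series,
                rqa_config=rqa_config,
                embedding_kwargs=embedding_kwargs,
                grid_size=grid_size,
                floor_fraction=floor_fraction,
            )
            for k, v in feats.items():
                row[f"{el}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Predictor columns: only dynamical features, never label or covariates."""
    suffixes = tuple(f"_{f}" for f in FEATURES)
    return [c for c in table.columns if c.endswith(suffixes)]


class DynamicsFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: sequence of {element: BiomarkerSeries} maps ->
    DataFrame of element x {n_states, det, mdl, ent} features.

    Parameters mirror :func:`extract_series_features`; ``fit`` only records
    the element set so the transformer is sklearn-pipeline compatible.
    """

    def __init__(
        self,
        target_recurrence_rate: float = 0.10,
        lmin: int = 3,
        norm: str = "euclidean",
        theiler_window: int = 1,
        grid_size: int = pot.GRID_SIZE,
        floor_fraction: float = pot.FLOOR_FRACTION,
    ):
        self.target_recurrence_rate = target_recurrence_rate
        self.lmin = lmin
        self.norm = norm
        self.theiler_window = theiler_window
        self.grid_size = grid_size
        self.floor_fraction = floor_fraction

    def _config(self) -> RQAConfig:
        return RQAConfig(
            target_recurrence_rate=self.target_recurrence_rate,
            lmin=self.lmin,
            norm=self.norm,
            theiler_window=self.theiler_window,
        )

    def fit(self, X, y=None):
        if len(X) == 0:
            raise ValueError("empty input")
        self.elements_ = sorted(X[0].keys())
        self.feature_names_out_ = [
            f"{el}_{f}" for el in self.elements_ for f in FEATURES
        ]
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "elements_"):
            raise RuntimeError("DynamicsFeaturizer is not fitted")
        cfg = self._config()
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for record in X:
                row = {}
                for el in self.elements_:
                    feats = extract_series_features(
                        record[el],
                        rqa_config=cfg,
                        grid_size=self.grid_size,
                        floor_fraction=self.floor_fraction,
                    )
                    for f in FEATURES:
                        row[f"{el}_{f}"] = feats[f]
                rows.append(row)
        return pd.DataFrame(rows, columns=self.feature_names_out_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_)
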