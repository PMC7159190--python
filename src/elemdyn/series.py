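"""Core container shared by every analysis stage.

A :class:`BiomarkerSeries` is one subject x element profile: an ordered time
axis in years since birth and a matched vector of calcium-normalised ion
counts (arbitrary units).  Every downstream stage -- delay embedding,
recurrence quantification, potential-landscape state counting -- consumes
this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BiomarkerSeries:
    """A univariate developmental time series for one subject and element.

    Parameters
    ----------
    time
        Strictly increasing sample times, in years since birth.
    values
        Measured intensities (finite reals), same length as ``time``.
    subject_id, element
        Free-text identifiers carried through the pipeline.
    """

    time: np.ndarray
    values: np.ndarray
    subject_id: str = ""
    element: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.ndim != 1 or self.values.ndim != 1:
            raise ValueError("time and values must be one-dimensional")
        if self.time.shape != self.values.shape:
            raise ValueError(
                f"time ({self.time.size}) and values ({self.values.size}) "
                "must have equal length"
            )
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_years": self.time, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, subject_id: str = "", element: str = "") -> "BiomarkerSeries":
        df = pd.read_csv(path)
        missing = {"time_years", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"series CSV {path} lacks columns {sorted(missing)}")
        return cls(
            time=df["time_years"].to_numpy(),
            values=df["value"].to_numpy(),
            subject_id=subject_id,
            element=element,
        )


@dataclass
class Subject:
    """One cohort member: label, covariates and a per-element series map."""

    subject_id: str
    group: str  # "case" or "control"
    covariates: dict = field(default_factory=dict)
    series: dict = field(default_factory=dict)  # element -> BiomarkerSeries
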