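"""Recurrence quantification analysis with an adaptive threshold.

A recurrence plot marks pairs of times whose embedded states lie within a
threshold ``epsilon`` of each other.  Here ``epsilon`` is adaptive: it is the
quantile of the pairwise distance distribution that realises a fixed target
recurrence rate (default 10%), which makes the derived features invariant to
affine rescaling of the input and comparable across elements.  Diagonal lines
of the plot encode cyclical recurrences; their length histogram P(l) yields

* determinism   DET = sum_{l>=lmin} l P(l) / sum_{l>=1} l P(l)
* mean diagonal length  MDL = sum_{l>=lmin} l P(l) / sum_{l>=lmin} P(l)
* diagonal entropy  ENT = -sum_{l>=lmin} p(l) ln p(l)

with ``lmin = 3`` successive measurements by default.

Conventions (configurable, stated here because published descriptions of RQA
vary): a Theiler window of ``w`` removes pairs with |i - j| < w, so the
default ``w = 1`` excludes exactly the line of identity; the diagonal-line
histogram counts the upper triangle only (the plot is symmetric); lines
truncated by the matrix border count at their observed length; entropy is
computed over l >= lmin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .embedding import EmbeddedTrajectory, EmbeddingParams, estimate_params, takens_embed
from .series import BiomarkerSeries

__all__ = [
    "RQAConfig",
    "RecurrenceResult",
    "adaptive_epsilon",
    "recurrence_matrix",
    "diagonal_histogram",
    "determinism",
    "mean_diagonal_length",
    "diagonal_entropy",
    "rqa_features",
]

_METRICS = {"euclidean": "euclidean", "maximum": "chebyshev", "chebyshev": "chebyshev"}


@dataclass(frozen=True)
class RQAConfig:
    target_recurrence_rate: float = 0.10
    lmin: int = 3
    norm: str = "euclidean"
    theiler_window: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.target_recurrence_rate <= 1.0:
            raise ValueError("target_recurrence_rate must be in (0, 1]")
        if self.lmin < 2:
            raise ValueError("lmin must be >= 2")
        if self.norm not in _METRICS:
            raise ValueError(f"norm must be one of {sorted(_METRICS)}")
        if self.theiler_window < 0:
            raise ValueError("theiler_window must be >= 0")


@dataclass
class RecurrenceResult:
    """Recurrence matrix plus the diagonal-line features derived from it."""

    matrix: np.ndarray
    epsilon: float
    recurrence_rate: float
    diag_histogram: dict | None = None
    determinism: float | None = None
    mean_diagonal_length: float | None = None
    entropy: float | None = None
    params: EmbeddingParams | None = None
    config: RQAConfig = field(default_factory=RQAConfig)

    @property
    def features(self) -> tuple:
        return (self.determinism, self.mean_diagonal_length, self.entropy)


def _points(trajectory) -> np.ndarray:
    if isinstance(trajectory, EmbeddedTrajectory):
        return trajectory.points
    pts = np.asarray(trajectory, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    return pts


def _distance_matrix(pts: np.ndarray, norm: str) -> np.ndarray:
    return squareform(pdist(pts, metric=_METRICS[norm]))


def _off_theiler_upper(n: int, theiler: int) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j), i < j, with j - i >= theiler."""
    iu, ju = np.triu_indices(n, k=max(theiler, 1))
    if theiler == 0:
        # include the main diagonal pairs as eligible self-recurrences
        di = np.arange(n)
        iu = np.concatenate([di, iu])
        ju = np.concatenate([di, ju])
    return iu, ju


def adaptive_epsilon(trajectory, config: RQAConfig = RQAConfig()) -> float:
    """Distance quantile realising the target recurrence rate.

    epsilon is the k-th smallest off-Theiler pairwise distance with
    k = floor(target * #pairs), so the realised rate matches the target up
    to the granularity of the finite distance set.
    """
    pts = _points(trajectory)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 embedded points")
    d = _distance_matrix(pts, config.norm)
    iu, ju = _off_theiler_upper(n, config.theiler_window)
    dists = d[iu, ju]
    if np.ptp(dists) == 0:
        raise ValueError(
            "degenerate geometry: all off-Theiler pairwise distances are equal"
        )
    k = max(1, int(math.floor(config.target_recurrence_rate * dists.size)))
    return float(np.partition(dists, k - 1)[k - 1])


def recurrence_matrix(
    trajectory, epsilon: float, config: RQAConfig = RQAConfig()
) -> RecurrenceResult:
    """Symmetric binary matrix: (i, j) = 1 iff d(i, j) <= epsilon and
    |i - j| >= theiler_window; the realised recurrence rate is reported over
    the off-Theiler pairs."""
    pts = _points(trajectory)
    n = len(pts)
    d = _distance_matrix(pts, config.norm)
    rec = d <= epsilon
    offsets = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    rec &= offsets >= config.theiler_window
    iu, ju = _off_theiler_upper(n, config.theiler_window)
    rate = float(np.mean(d[iu, ju] <= epsilon))
    params = trajectory.params if isinstance(trajectory, EmbeddedTrajectory) else None
    return RecurrenceResult(
        matrix=rec, epsilon=float(epsilon), recurrence_rate=rate,
        params=params, config=config,
    )


def _run_lengths(binary: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of ones in a 1-D binary array."""
    padded = np.concatenate(([0], binary.astype(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    return edges[1::2] - edges[::2]


def diagonal_histogram(matrix: np.ndarray, theiler_window: int = 1) -> dict:
    """Histogram P(l) of maximal diagonal-line lengths, upper triangle only.

    Superdiagonals k >= max(theiler_window, 1) are scanned; the symmetric
    lower triangle would duplicate every line and is not counted.
    """
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    hist: dict[int, int] = {}
    for k in range(max(theiler_window, 1), n):
        for length in _run_lengths(np.diagonal(matrix, offset=k)):
            hist[int(length)] = hist.get(int(length), 0) + 1
    return hist


def determinism(P: Mapping[int, int], lmin: int = 3) -> float:
    """Share of recurrent points on diagonal lines of length >= lmin."""
    total = sum(l * c for l, c in P.items())
    if total == 0:
        return float("nan")
    long = sum(l * c for l, c in P.items() if l >= lmin)
    return long / total


def mean_diagonal_length(P: Mapping[int, int], lmin: int = 3) -> float:
    """Average length of qualifying diagonal lines (NaN when none qualify)."""
    count = sum(c for l, c in P.items() if l >= lmin)
    if count == 0:
        return float("nan")
    return sum(l * c for l, c in P.items() if l >= lmin) / count


def diagonal_entropy(P: Mapping[int, int], lmin: int = 3) -> float:
    """Shannon entropy (nats) of the line-length distribution over l >= lmin."""
    counts = np.array([c for l, c in P.items() if l >= lmin], dtype=float)
    if counts.size == 0 or counts.sum() == 0:
        return float("nan")
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def rqa_features(
    series,
    params: EmbeddingParams | None = None,
    config: RQAConfig = RQAConfig(),
    **estimate_kwargs,
) -> RecurrenceResult:
    """End-to-end pipeline: embed, adapt epsilon, build the plot, derive
    DET / MDL / ENT.  When ``params`` is None, (tau, m) are estimated from
    the series (AMI minimum, FNN minimisation)."""
    z = series.values if isinstance(series, BiomarkerSeries) else np.asarray(series, float)
    if np.ptp(z) == 0:
        raise ValueError("constant series: recurrence geometry is degenerate")
    if params is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            params = estimate_params(z, **estimate_kwargs)
    traj = takens_embed(z, params)
    eps = adaptive_epsilon(traj, config)
    result = recurrence_matrix(traj, eps, config)
    result.diag_histogram = diagonal_histogram(result.matrix, config.theiler_window)
    result.determinism = determinism(result.diag_histogram, config.lmin)
    result.mean_diagonal_length = mean_diagonal_length(result.diag_histogram, config.lmin)
    result.entropy = diagonal_entropy(result.diag_histogram, config.lmin)
    result.params = params
    return result
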