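"""Phase-space reconstruction by Takens delay embedding.

The delay ``tau`` is chosen as the first local minimum of the average mutual
information (AMI) between the series and its lagged copy; the embedding
dimension ``m`` as the smallest dimension at which the false-nearest-neighbour
(FNN) fraction, per the Kennel criteria, drops below a threshold.  Both are
estimated per series; defaults (16 equal-width AMI bins, rtol = 10, atol = 2,
1% FNN threshold) follow common convention and are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .series import BiomarkerSeries

__all__ = [
    "EmbeddingParams",
    "EmbeddedTrajectory",
    "average_mutual_information",
    "estimate_delay",
    "fnn_fraction",
    "estimate_dimension",
    "takens_embed",
    "estimate_params",
]


def _values(series) -> np.ndarray:
    if isinstance(series, BiomarkerSeries):
        return series.values
    return np.asarray(series, dtype=float)


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay ``tau`` (samples) and dimension ``m`` of a Takens embedding."""

    delay: int
    dimension: int

    def __post_init__(self) -> None:
        if self.delay < 1:
            raise ValueError("delay must be >= 1")
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")


@dataclass
class EmbeddedTrajectory:
    """Point cloud of lagged coordinates; row i = (z_i, z_{i+tau}, ..., z_{i+(m-1)tau})."""

    points: np.ndarray
    params: EmbeddingParams


def takens_embed(series, params: EmbeddingParams) -> EmbeddedTrajectory:
    """Build the delay-coordinate matrix; rows = n - (m - 1) * tau."""
    z = _values(series)
    n = z.size
    m, tau = params.dimension, params.delay
    n_rows = n - (m - 1) * tau
    if n_rows < 1:
        raise ValueError(
            f"embedding infeasible: series length n={n} with m={m}, tau={tau} "
            f"leaves {n_rows} rows"
        )
    points = np.empty((n_rows, m))
    for j in range(m):
        points[:, j] = z[j * tau : j * tau + n_rows]
    return EmbeddedTrajectory(points=points, params=params)


# --------------------------------------------------------------------------
# Average mutual information and delay selection
# --------------------------------------------------------------------------

def _bin_edges(z: np.ndarray, bins: int, strategy: str) -> np.ndarray:
    if strategy == "width":
        return np.linspace(z.min(), z.max(), bins + 1)
    if strategy == "quantile":
        edges = np.quantile(z, np.linspace(0.0, 1.0, bins + 1))
        return np.unique(edges)
    raise ValueError(f"unknown binning strategy {strategy!r}")


def average_mutual_information(
    series, lag: int, bins: int = 16, strategy: str = "width"
) -> float:
    """AMI (nats) between z_t and z_{t+lag} from a joint histogram.

    Bin edges are shared between the two marginals and derived from the full
    series, so AMI at lag 0 equals the marginal histogram entropy.  With
    ``strategy="quantile"`` the estimate is invariant under strictly
    monotone rescaling of the values.
    """
    z = _values(series)
    n = z.size
    if not 0 <= lag < n:
        raise ValueError(f"lag must be in [0, {n}), got {lag}")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if np.ptp(z) == 0:
        warnings.warn(
            "constant series: AMI is undefined, returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    lag = abs(lag)
    x, y = z[: n - lag], z[lag:]
    edges = _bin_edges(z, bins, strategy)
    joint, _, _ = np.histogram2d(x, y, bins=[edges, edges])
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    outer = np.outer(px, py)
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / outer[nz])))


class DelayEstimate(NamedTuple):
    delay: int
    warned: bool
    ami: np.ndarray  # AMI at lags 0..max_lag


def _first_local_minimum(curve: np.ndarray) -> int | None:
    """Smallest index k >= 1 that is a strict local minimum; plateaus take
    their left edge (strict drop into the plateau, strict rise out of it)."""
    n = len(curve)
    k = 1
    while k < n - 1:
        if curve[k] < curve[k - 1]:
            j = k
            while j + 1 < n and curve[j + 1] == curve[k]:
                j += 1
            if j + 1 < n and curve[j + 1] > curve[k]:
                return k
            k = j + 1
        else:
            k += 1
    return None


def estimate_delay(
    series,
    max_lag: int,
    bins: int = 16,
    strategy: str = "width",
    full_output: bool = False,
):
    """First local minimum of the AMI curve over lags 1..max_lag.

    Falls back to the global minimiser (with a warning) when the curve has
    no interior local minimum, e.g. for monotone trends.
    """
    z = _values(series)
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2")
    if z.size < max_lag + 2:
        raise ValueError(
            f"series of length {z.size} too short for max_lag={max_lag}"
        )
    ami = np.array(
        [average_mutual_information(z, lag, bins, strategy) for lag in range(max_lag + 1)]
    )
    k = _first_local_minimum(ami)
    warned = False
    if k is None:
        k = int(1 + np.argmin(ami[1:]))
        warned = True
        warnings.warn(
            "AMI curve has no interior local minimum; using the global "
            f"minimiser lag={k}",
            RuntimeWarning,
            stacklevel=2,
        )
    result = DelayEstimate(delay=int(k), warned=warned, ami=ami)
    return result if full_output else result.delay


# --------------------------------------------------------------------------
# False nearest neighbours and dimension selection
# --------------------------------------------------------------------------

def fnn_fraction(
    series, delay: int, dim: int, rtol: float = 10.0, atol: float = 2.0
) -> float:
    """Fraction of nearest neighbours at dimension ``dim`` that are false
    when the embedding is lifted to ``dim + 1`` (Kennel criteria).

    A neighbour pair is false when the extra coordinate inflates its
    distance by more than ``rtol`` relative to the dim-dimensional distance,
    or beyond ``atol`` attractor sizes (SD of the series) in absolute terms.
    """
    z = _values(series)
    n = z.size
    tau = delay
    n_lift = n - dim * tau  # points embeddable at dim + 1
    if n_lift < 10:
        raise ValueError(
            f"fewer than 10 embedded points at dimension {dim + 1} "
            f"(n={n}, tau={tau})"
        )
    if np.ptp(z) == 0:
        warnings.warn(
            "constant series: all distances are zero, FNN fraction is 0 by "
            "convention",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    pts = takens_embed(z, EmbeddingParams(delay=tau, dimension=dim)).points[:n_lift]
    extra = z[dim * tau : dim * tau + n_lift]
    tree = cKDTree(pts)
    dist, idx = tree.query(pts, k=2)
    d_m = dist[:, 1]
    nn = idx[:, 1]
    gap = np.abs(extra - extra[nn])
    r_a = float(np.std(z))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d_m > 0, gap / d_m, np.where(gap > 0, np.inf, 0.0))
    d_lift = np.sqrt(d_m**2 + gap**2)
    false = (ratio > rtol) | (d_lift / r_a > atol)
    # numerically coincident pairs (noiseless periodic signals revisit states
    # to within float rounding) are genuine neighbours, whatever the ratio
    false &= d_lift > 1e-8 * r_a
    return float(np.mean(false))


class DimensionEstimate(NamedTuple):
    dimension: int
    warned: bool
    fractions: dict  # dim -> FNN fraction


def estimate_dimension(
    series,
    delay: int,
    max_dim: int = 6,
    rtol: float = 10.0,
    atol: float = 2.0,
    threshold: float = 0.01,
    full_output: bool = False,
):
    """Smallest m <= max_dim with FNN fraction below ``threshold``.

    Returns max_dim (or the largest feasible dimension) with a warning when
    no dimension passes; a constant series is 1-dimensional by convention.
    """
    z = _values(series)
    if max_dim < 1:
        raise ValueError("max_dim must be >= 1")
    if np.ptp(z) == 0:
        warnings.warn(
            "constant series: embedding dimension 1 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
        result = DimensionEstimate(dimension=1, warned=True, fractions={})
        return result if full_output else result.dimension
    fractions: dict[int, float] = {}
    last_feasible = None
    for m in range(1, max_dim + 1):
        try:
            frac = fnn_fraction(z, delay, m, rtol=rtol, atol=atol)
        except ValueError:
            break
        fractions[m] = frac
        last_feasible = m
        if frac < threshold:
            result = DimensionEstimate(dimension=m, warned=False, fractions=fractions)
            return result if full_output else result.dimension
    if last_feasible is None:
        raise ValueError("series too short to embed at dimension 2")
    warnings.warn(
        f"no dimension <= {max_dim} reached FNN fraction < {threshold}; "
        f"returning {last_feasible}",
        RuntimeWarning,
        stacklevel=2,
    )
    result = DimensionEstimate(dimension=last_feasible, warned=True, fractions=fractions)
    return result if full_output else result.dimension


def estimate_params(
    series,
    max_lag: int | None = None,
    max_dim: int = 6,
    bins: int = 16,
    rtol: float = 10.0,
    atol: float = 2.0,
    threshold: float = 0.01,
) -> EmbeddingParams:
    """Joint (tau, m) selection: AMI minimum then FNN minimisation."""
    z = _values(series)
    n = z.size
    if max_lag is None:
        max_lag = int(max(2, min(50, n // 10)))
    tau = estimate_delay(z, max_lag=max_lag, bins=bins)
    # keep the embedding window well inside the series
    while (max_dim - 1) * tau >= n - 10 and max_dim > 1:
        max_dim -= 1
    m = estimate_dimension(
        z, delay=tau, max_dim=max_dim, rtol=rtol, atol=atol, threshold=threshold
    )
    return EmbeddingParams(delay=tau, dimension=m)
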