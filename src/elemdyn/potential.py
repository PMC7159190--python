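"""Potential-energy landscapes and quasi-stable state counting.

The series is modelled as an overdamped stochastic system whose stationary
probability density Pd determines an effective potential through the
Fokker-Planck steady state, U = -(sigma^2 / 2) log Pd.  With the series
standardised to unit SD and the potential reported on the noise scale
(U / sigma^2), this reduces to U = -log(Pd) / 2.  Local minima of U are
quasi-stable attractor states; local maxima are the tipping points between
them.  The number of minima is the state count fed to the group statistics.

Pd is a Gaussian KDE with Scott's bandwidth (n^(-1/5) * SD) evaluated on a
500-point grid spanning the data range padded by three bandwidths.  Because
-log Pd diverges in empty tails and would manufacture spurious extrema,
grid regions with density below ``floor_fraction`` (default 0.02) of the
density maximum are excluded from the extremum search.  The floor is sized
so that the kernel bump of one or two isolated tail points -- whose relative
density at n ~ 500 and Scott bandwidth is about (n h pmax sqrt(2 pi))^-1,
i.e. just under 1% of the maximum -- cannot register as a state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .series import BiomarkerSeries

__all__ = [
    "PotentialLandscape",
    "RollingLandscape",
    "standardize",
    "estimate_density",
    "potential_from_density",
    "find_states",
    "landscape",
    "rolling_landscape",
    "count_states",
]

GRID_SIZE = 500
FLOOR_FRACTION = 0.02


@dataclass
class PotentialLandscape:
    grid: np.ndarray
    density: np.ndarray
    potential: np.ndarray
    minima: np.ndarray  # grid locations of quasi-stable states
    maxima: np.ndarray  # grid locations of tipping points

    @property
    def n_states(self) -> int:
        return len(self.minima)


@dataclass
class RollingLandscape:
    """Per-window landscapes on one shared (standardised) grid."""

    grid: np.ndarray
    window_centers: np.ndarray  # time (years) at each window centre
    potentials: np.ndarray  # (n_windows, grid_size)
    densities: np.ndarray  # (n_windows, grid_size)
    n_states: np.ndarray  # per-window state count
    window_length: int
    step: int


def standardize(series: BiomarkerSeries, return_params: bool = False):
    """Centre and scale to unit sample SD (ddof=1).

    The landscape is invariant to affine rescaling of the input, so this
    only fixes the noise scale sigma = 1 used by the potential formula.
    """
    sd = float(np.std(series.values, ddof=1))
    if sd == 0:
        raise ValueError("constant series cannot be standardized (zero variance)")
    mean = float(np.mean(series.values))
    out = BiomarkerSeries(
        time=series.time,
        values=(series.values - mean) / sd,
        subject_id=series.subject_id,
        element=series.element,
    )
    return (out, mean, sd) if return_params else out


def estimate_density(values, grid_size: int = GRID_SIZE):
    """Gaussian KDE with Scott's bandwidth on a padded uniform grid."""
    z = np.asarray(values, dtype=float)
    if np.unique(z).size < 10:
        raise ValueError("need at least 10 distinct values for density estimation")
    kde = gaussian_kde(z, bw_method="scott")
    bw = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(z.min() - 3.0 * bw, z.max() + 3.0 * bw, grid_size)
    density = kde(grid)
    return grid, density


def potential_from_density(density, sigma: float = 1.0) -> np.ndarray:
    """U = -(sigma^2 / 2) ln Pd, reported on the noise scale U / sigma^2.

    Zero densities map to +inf; callers exclude those regions with the
    density floor before searching for extrema.
    """
    pd_arr = np.asarray(density, dtype=float)
    with np.errstate(divide="ignore"):
        return -0.5 * np.log(pd_arr)


def _interior_extrema(u: np.ndarray):
    """Indices of strict interior minima/maxima; plateaus collapse to their
    left edge."""
    # compress exact plateaus so each flat stretch contributes one candidate
    keep = np.concatenate(([True], np.diff(u) != 0))
    comp_idx = np.flatnonzero(keep)
    uc = u[comp_idx]
    if uc.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    d = np.sign(np.diff(uc))
    minima = comp_idx[1:-1][(d[:-1] < 0) & (d[1:] > 0)]
    maxima = comp_idx[1:-1][(d[:-1] > 0) & (d[1:] < 0)]
    return minima, maxima


def find_states(
    grid,
    potential,
    density,
    floor_fraction: float = FLOOR_FRACTION,
):
    """Locate quasi-stable states (minima of U) and tipping points (maxima).

    Candidate extrema come from first-difference sign changes of U; minima in
    regions where the density is below ``floor_fraction`` of its maximum are
    discarded as tail artefacts.  One tipping point -- the potential argmax
    strictly between them -- is reported for each adjacent pair of retained
    minima, so minima and maxima always alternate.  A proper density yields
    at least one state: when no interior minimum survives, the global
    minimum of U over the supported region is reported alone.
    """
    grid = np.asarray(grid, dtype=float)
    u = np.asarray(potential, dtype=float)
    pd_arr = np.asarray(density, dtype=float)
    if grid.size < 10:
        raise ValueError("potential must be defined on >= 10 grid points")
    supported = pd_arr >= floor_fraction * pd_arr.max()

    min_idx, _ = _interior_extrema(u)
    min_idx = np.array([i for i in min_idx if supported[i]], dtype=int)

    if min_idx.size == 0:
        sup_idx = np.flatnonzero(supported)
        gmin = sup_idx[np.argmin(u[sup_idx])]
        return grid[[gmin]], grid[[]].copy(), 1

    max_idx = []
    for a, b in zip(min_idx[:-1], min_idx[1:]):
        seg = u[a + 1 : b]
        max_idx.append(a + 1 + int(np.argmax(seg)))
    max_idx = np.asarray(max_idx, dtype=int)
    return grid[min_idx], grid[max_idx], int(min_idx.size)


def landscape(
    series: BiomarkerSeries,
    grid_size: int = GRID_SIZE,
    floor_fraction: float = FLOOR_FRACTION,
) -> PotentialLandscape:
    """standardise -> KDE -> potential -> state location, on the full series."""
    std = standardize(series)
    grid, density = estimate_density(std.values, grid_size=grid_size)
    u = potential_from_density(density)
    minima, maxima, _ = find_states(grid, u, density, floor_fraction)
    return PotentialLandscape(
        grid=grid, density=density, potential=u, minima=minima, maxima=maxima
    )


def count_states(
    series: BiomarkerSeries,
    grid_size: int = GRID_SIZE,
    floor_fraction: float = FLOOR_FRACTION,
) -> int:
    """Number of quasi-stable states in the full-series landscape."""
    return landscape(series, grid_size=grid_size, floor_fraction=floor_fraction).n_states


def rolling_landscape(
    series: BiomarkerSeries,
    window_length: int = 50,
    step: int = 1,
    grid_size: int = GRID_SIZE,
    floor_fraction: float = FLOOR_FRACTION,
) -> RollingLandscape:
    """Landscapes in rolling windows, for rendering state formation over time.

    Each window is standardised on its own scale (windows are then
    comparable in units of their local SD) and evaluated on one shared grid
    wide enough for every window.
    """
    n = series.n
    if window_length > n:
        raise ValueError(f"window_length {window_length} exceeds series length {n}")
    if window_length < 10:
        raise ValueError("window_length must be >= 10")
    starts = np.arange(0, n - window_length + 1, step)

    std_windows = []
    lo, hi = np.inf, -np.inf
    for s in starts:
        w = series.values[s : s + window_length]
        sd = np.std(w, ddof=1)
        if sd == 0:
            raise ValueError(f"window starting at index {s} is constant")
        zw = (w - w.mean()) / sd
        bw = np.std(zw, ddof=1) * window_length ** (-0.2)
        std_windows.append(zw)
        lo = min(lo, zw.min() - 3.0 * bw)
        hi = max(hi, zw.max() + 3.0 * bw)
    grid = np.linspace(lo, hi, grid_size)

    potentials = np.empty((len(starts), grid_size))
    densities = np.empty((len(starts), grid_size))
    n_states = np.empty(len(starts), dtype=int)
    centers = np.empty(len(starts))
    for i, (s, zw) in enumerate(zip(starts, std_windows)):
        density = gaussian_kde(zw, bw_method="scott")(grid)
        u = potential_from_density(density)
        _, _, k = find_states(grid, u, density, floor_fraction)
        densities[i] = density
        potentials[i] = u
        n_states[i] = k
        centers[i] = series.time[s : s + window_length].mean()
    return RollingLandscape(
        grid=grid,
        window_centers=centers,
        potentials=potentials,
        densities=densities,
        n_states=n_states,
        window_length=window_length,
        step=step,
    )
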