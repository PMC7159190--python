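"""Synthetic biomarker-series and cohort generators.

The real dentine profiles behind this kind of analysis are not publicly
deposited, so the package ships generators that reproduce their statistical
structure: per-subject series of 300-600 samples spanning roughly 0-14 years,
either *bistable* (a stochastic particle in a double-well potential that
switches between a high- and a low-concentration regime), *mono-stable*
(a single confining well, Ornstein-Uhlenbeck-like), or *oscillatory*
(piecewise sinusoids that shift from a slow- to a fast-cycling regime).
Cohorts combine these per element and group with planted case/control
differences plus sex and age covariates.

All generators are deterministic given their integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .series import BiomarkerSeries, Subject

__all__ = [
    "WellSpec",
    "RegimeSwitchSpec",
    "GeneratorSpec",
    "CohortSpec",
    "simulate_langevin",
    "simulate_regime_switch",
    "simulate_cohort",
    "GENERATORS",
    "planted_cohort_spec",
    "null_cohort_spec",
]


# --------------------------------------------------------------------------
# Langevin dynamics in a polynomial potential
# --------------------------------------------------------------------------

@dataclass
class WellSpec:
    """A scalar stochastic system dz = -V'(z) dt + sigma dW.

    ``potential_coefficients`` are the coefficients of the deterministic
    potential V(z) in *ascending* powers (numpy polynomial convention); the
    drift is the negative gradient -V'(z).  V must be confining: even degree
    >= 2 with a positive leading coefficient, so trajectories cannot escape
    to infinity.
    """

    potential_coefficients: Sequence[float]
    noise_sigma: float
    z0: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.potential_coefficients, dtype=float)
        c = np.trim_zeros(c, trim="b")
        if c.size < 3:
            raise ValueError("potential must have polynomial degree >= 2")
        degree = c.size - 1
        if degree % 2 != 0 or c[-1] <= 0:
            raise ValueError(
                "potential is not confining: need even degree with a "
                "positive leading coefficient"
            )
        if not self.noise_sigma > 0:
            raise ValueError("noise_sigma must be > 0")
        self._coeffs = c

    def potential(self, z):
        return np.polynomial.polynomial.polyval(z, self._coeffs)

    def drift(self, z):
        d1 = np.polynomial.polynomial.polyder(self._coeffs)
        return -np.polynomial.polynomial.polyval(z, d1)

    def curvature(self, z):
        d2 = np.polynomial.polynomial.polyder(self._coeffs, 2)
        return np.polynomial.polynomial.polyval(z, d2)

    def stationary_density(self, z):
        """Unnormalised stationary density exp(-2 V(z) / sigma^2)."""
        return np.exp(-2.0 * self.potential(z) / self.noise_sigma**2)


def simulate_langevin(
    spec: WellSpec,
    n: int,
    dt: float,
    seed: int,
    *,
    substeps: int = 1,
    blowup_bound: float = 1e4,
    subject_id: str = "",
    element: str = "",
) -> BiomarkerSeries:
    """Integrate dz = -V'(z) dt + sigma dW by Euler-Maruyama.

    ``n`` samples are emitted on the uniform grid ``time = index * dt``;
    ``substeps`` internal steps of size ``dt / substeps`` are taken between
    emitted samples to control integrator bias.  After the run the explicit
    stability condition ``h * max|V''| < 2`` (h the internal step) is checked
    over the visited range and a warning is emitted if it fails.

    Raises
    ------
    RuntimeError
        If the trajectory exceeds ``blowup_bound`` in magnitude, which
        indicates the step size ``dt`` is too large for the potential.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")

    rng = np.random.default_rng(seed)
    h = dt / substeps
    sqrt_h = np.sqrt(h)
    sigma = spec.noise_sigma
    # derivative of V, ascending coefficients, as plain floats for the hot loop
    dcoeffs = [float(k * c) for k, c in enumerate(spec._coeffs)][1:]
    dcoeffs_rev = dcoeffs[::-1]

    noise = rng.standard_normal((n - 1) * substeps)
    out = np.empty(n)
    z = float(spec.z0)
    out[0] = z
    zmin = zmax = z
    idx = 0
    for i in range(1, n):
        for _ in range(substeps):
            dv = 0.0
            for c in dcoeffs_rev:  # Horner evaluation of V'(z)
                dv = dv * z + c
            z = z - dv * h + sigma * sqrt_h * noise[idx]
            idx += 1
            if abs(z) > blowup_bound:
                raise RuntimeError(
                    f"trajectory exceeded |z| = {blowup_bound:g}: the step "
                    f"dt = {dt:g} (substeps = {substeps}) is too large for "
                    "this potential"
                )
        out[i] = z
        zmin = min(zmin, z)
        zmax = max(zmax, z)

    zgrid = np.linspace(zmin, zmax, 512)
    max_curv = float(np.max(np.abs(spec.curvature(zgrid))))
    if h * max_curv >= 2.0:
        warnings.warn(
            f"Euler-Maruyama stability check failed: step {h:g} * max|V''| "
            f"{max_curv:.3g} >= 2 on the visited range [{zmin:.3g}, {zmax:.3g}]",
            RuntimeWarning,
            stacklevel=2,
        )
    return BiomarkerSeries(
        time=np.arange(n) * dt, values=out, subject_id=subject_id, element=element
    )


# --------------------------------------------------------------------------
# Piecewise oscillatory series
# --------------------------------------------------------------------------

@dataclass
class RegimeSwitchSpec:
    """Piecewise sinusoid + Gaussian noise with abrupt regime switches.

    Segment k runs from ``switch_times[k-1]`` (0 for the first) and produces
    ``means[k] + amplitudes[k] * sin(2 pi frequencies[k] (t - t_start_k))``;
    the phase resets at each switch.  Emulates a shift from a slow-cycling
    high-mean regime to a fast-cycling low-mean regime.
    """

    segment_frequencies: Sequence[float]  # cycles per year
    segment_means: Sequence[float]
    segment_amplitudes: Sequence[float]
    switch_times: Sequence[float] = ()  # years, strictly increasing
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        k = len(self.segment_frequencies)
        if not (len(self.segment_means) == len(self.segment_amplitudes) == k):
            raise ValueError("segment parameter lists must have equal length")
        if len(self.switch_times) != k - 1:
            raise ValueError(
                f"{k} segments require {k - 1} switch times, "
                f"got {len(self.switch_times)}"
            )
        st = np.asarray(self.switch_times, dtype=float)
        if st.size and np.any(np.diff(st) <= 0):
            raise ValueError("switch_times must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_regime_switch(
    spec: RegimeSwitchSpec,
    n: int,
    t_max: float,
    seed: int,
    *,
    subject_id: str = "",
    element: str = "",
) -> BiomarkerSeries:
    """Sample a regime-switching sinusoid on a uniform grid over [0, t_max)."""
    if n < 10:
        raise ValueError("n must be >= 10")
    st = np.asarray(spec.switch_times, dtype=float)
    if st.size and t_max <= st[-1]:
        raise ValueError("t_max must exceed the last switch time")

    rng = np.random.default_rng(seed)
    t = np.arange(n) * (t_max / n)
    seg = np.searchsorted(st, t, side="right")
    starts = np.concatenate(([0.0], st))
    freqs = np.asarray(spec.segment_frequencies, dtype=float)
    means = np.asarray(spec.segment_means, dtype=float)
    amps = np.asarray(spec.segment_amplitudes, dtype=float)
    values = means[seg] + amps[seg] * np.sin(
        2.0 * np.pi * freqs[seg] * (t - starts[seg])
    )
    if spec.noise_sd > 0:
        values = values + spec.noise_sd * rng.standard_normal(n)
    return BiomarkerSeries(time=t, values=values, subject_id=subject_id, element=element)


# --------------------------------------------------------------------------
# Named generators used in cohort assembly
# --------------------------------------------------------------------------

def _gen_bistable_well(
    n: int,
    seed: int,
    sampling_interval: float,
    *,
    barrier: float = 1.0,
    sigma: float = 1.0,
    dt: float = 0.3,
    substeps: int = 10,
    tilt: float = 0.0,
    z0: float = -1.0,
) -> BiomarkerSeries:
    """Quartic double well V(z) = barrier * (z^4 - 2 z^2) + tilt * z.

    With the defaults (barrier 1, sigma 1, 0.3 model-time units per emitted
    sample) the Kramers escape time (~8 model-time units) is short against
    the record length, so a 300-600 sample series switches basins many
    times and occupies both wells -- the bistable phenomenology the analysis
    targets.  A positive ``tilt`` deepens the left well and starves the
    right one, degrading the system towards mono-stability.
    """
    spec = WellSpec(
        potential_coefficients=[0.0, tilt, -2.0 * barrier, 0.0, barrier],
        noise_sigma=sigma,
        z0=z0,
    )
    s = simulate_langevin(spec, n, dt, seed, substeps=substeps)
    return BiomarkerSeries(time=np.arange(n) * sampling_interval, values=s.values)


def _gen_monostable_well(
    n: int,
    seed: int,
    sampling_interval: float,
    *,
    stiffness: float = 1.0,
    sigma: float = 1.0,
    dt: float = 0.3,
    substeps: int = 10,
    z0: float = 0.0,
) -> BiomarkerSeries:
    """Single quadratic well V(z) = stiffness * z^2 / 2 (OU process)."""
    spec = WellSpec(
        potential_coefficients=[0.0, 0.0, stiffness / 2.0],
        noise_sigma=sigma,
        z0=z0,
    )
    s = simulate_langevin(spec, n, dt, seed, substeps=substeps)
    return BiomarkerSeries(time=np.arange(n) * sampling_interval, values=s.values)


def _gen_oscillation(
    n: int,
    seed: int,
    sampling_interval: float,
    *,
    freqs: Sequence[float] = (3.0,),
    means: Sequence[float] = (0.0,),
    amps: Sequence[float] = (0.4,),
    switch_fracs: Sequence[float] = (),
    noise_sd: float = 0.2,
) -> BiomarkerSeries:
    """Regime-switching sinusoid; switch times given as fractions of the span."""
    t_max = n * sampling_interval
    spec = RegimeSwitchSpec(
        segment_frequencies=freqs,
        segment_means=means,
        segment_amplitudes=amps,
        switch_times=[f * t_max for f in switch_fracs],
        noise_sd=noise_sd,
    )
    return simulate_regime_switch(spec, n, t_max, seed)


GENERATORS: dict[str, Callable[..., BiomarkerSeries]] = {
    "bistable_well": _gen_bistable_well,
    "monostable_well": _gen_monostable_well,
    "oscillation": _gen_oscillation,
}


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass
class GeneratorSpec:
    name: str
    params: dict = field(default_factory=dict)


@dataclass
class CohortSpec:
    """A case/control cohort design.

    ``assignments`` maps element -> {"case": GeneratorSpec, "control":
    GeneratorSpec}.  Series lengths are drawn per subject from
    ``length_range`` (inclusive) to mimic the unequal developmental windows
    of real tooth samples; every element of one subject shares that length.
    """

    n_cases: int
    n_controls: int
    elements: Sequence[str]
    assignments: Mapping[str, Mapping[str, GeneratorSpec]]
    sex_p: float = 0.5
    age_mean: float = 55.0
    age_sd: float = 10.0
    smoking_p: float | None = None
    length_range: tuple[int, int] = (300, 600)
    sampling_interval: float = 0.021  # years per sample (~weekly)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        for el in self.elements:
            if el not in self.assignments:
                raise ValueError(f"element {el!r} has no generator assignment")
            for grp in ("case", "control"):
                if grp not in self.assignments[el]:
                    raise ValueError(
                        f"element {el!r} lacks a generator for group {grp!r}"
                    )
                gs = self.assignments[el][grp]
                if gs.name not in GENERATORS:
                    raise ValueError(
                        f"unknown generator {gs.name!r}; available: "
                        f"{sorted(GENERATORS)}"
                    )
        lo, hi = self.length_range
        if not (10 <= lo <= hi):
            raise ValueError("length_range must satisfy 10 <= lo <= hi")


def simulate_cohort(spec: CohortSpec) -> list[Subject]:
    """Generate the full cohort; bit-reproducible for a given spec seed."""
    master = np.random.default_rng(spec.seed)
    subjects: list[Subject] = []
    groups = ["case"] * spec.n_cases + ["control"] * spec.n_controls
    lo, hi = spec.length_range
    for i, group in enumerate(groups):
        sid = f"{'case' if group == 'case' else 'ctrl'}_{i + 1:03d}"
        n = int(master.integers(lo, hi + 1))
        cov = {
            "sex": int(master.random() < spec.sex_p),
            "age": float(master.normal(spec.age_mean, spec.age_sd)),
        }
        if spec.smoking_p is not None:
            cov["smoking"] = int(master.random() < spec.smoking_p)
        series = {}
        for el in spec.elements:
            gs = spec.assignments[el][group]
            gen_seed = int(master.integers(2**31))
            s = GENERATORS[gs.name](
                n, gen_seed, spec.sampling_interval, **gs.params
            )
            series[el] = BiomarkerSeries(
                time=s.time, values=s.values, subject_id=sid, element=el
            )
        subjects.append(Subject(subject_id=sid, group=group, covariates=cov, series=series))
    return subjects


ELEMENTS = ("Cu", "Li", "Mg", "Mn", "Zn")


def planted_cohort_spec(seed: int = 0, n_cases: int = 36, n_controls: int = 31) -> CohortSpec:
    """Cohort with the two planted case/control contrasts the analysis targets.

    Copper: controls bistable, cases mono-stable (state-count effect).
    Magnesium / manganese: identical oscillatory dynamics but a weaker
    signal-to-noise ratio in cases (determinism/entropy effect).  Lithium
    carries a mild state effect (shallower case barrier); zinc is null.
    """
    osc_slow_fast = dict(freqs=[2.0, 5.0], means=[0.0, 0.0], amps=[0.5, 0.4],
                         switch_fracs=[0.5])
    assignments = {
        "Cu": {
            "control": GeneratorSpec("bistable_well"),
            "case": GeneratorSpec("monostable_well"),
        },
        "Li": {
            "control": GeneratorSpec("bistable_well"),
            "case": GeneratorSpec("bistable_well", {"tilt": 0.7}),
        },
        "Mg": {
            "control": GeneratorSpec("oscillation", dict(noise_sd=0.15, **osc_slow_fast)),
            "case": GeneratorSpec("oscillation", dict(noise_sd=0.4, **osc_slow_fast)),
        },
        "Mn": {
            "control": GeneratorSpec(
                "oscillation",
                dict(freqs=[3.0], means=[0.0], amps=[0.5], noise_sd=0.12),
            ),
            "case": GeneratorSpec(
                "oscillation",
                dict(freqs=[3.0], means=[0.0], amps=[0.5], noise_sd=0.3),
            ),
        },
        "Zn": {
            "control": GeneratorSpec(
                "oscillation",
                dict(freqs=[3.0], means=[0.0], amps=[0.5], noise_sd=0.2),
            ),
            "case": GeneratorSpec(
                "oscillation",
                dict(freqs=[3.0], means=[0.0], amps=[0.5], noise_sd=0.2),
            ),
        },
    }
    return CohortSpec(
        n_cases=n_cases,
        n_controls=n_controls,
        elements=ELEMENTS,
        assignments=assignments,
        seed=seed,
    )


def null_cohort_spec(
    seed: int = 0,
    n_cases: int = 36,
    n_controls: int = 31,
    elements: Sequence[str] = ELEMENTS,
    length_range: tuple[int, int] = (300, 600),
) -> CohortSpec:
    """Cohort in which case and control generators are identical per element."""
    per_element = {
        "Cu": GeneratorSpec("bistable_well"),
        "Li": GeneratorSpec("bistable_well"),
        "Mg": GeneratorSpec(
            "oscillation",
            dict(freqs=[2.0, 5.0], means=[0.0, 0.0], amps=[0.5, 0.4],
                 switch_fracs=[0.5], noise_sd=0.15),
        ),
        "Mn": GeneratorSpec(
            "oscillation", dict(freqs=[3.0], means=[0.0], amps=[0.5], noise_sd=0.12)
        ),
        "Zn": GeneratorSpec(
            "oscillation", dict(freqs=[3.0], means=[0.0], amps=[0.5], noise_sd=0.2)
        ),
    }
    assignments = {
        el: {"case": per_element[el], "control": per_element[el]} for el in elements
    }
    return CohortSpec(
        n_cases=n_cases,
        n_controls=n_controls,
        elements=tuple(elements),
        assignments=assignments,
        length_range=length_range,
        seed=seed,
    )
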