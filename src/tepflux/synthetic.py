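"""Synthetic TEP count tables, time series and trap compositions.

Raw microscopy count tables and trap dry masses from minicosm experiments
are rarely published, so every analysis stage in this package is exercised
against simulated data with the statistical structure the analysis
assumes:

* TEP counts follow a power-law number size distribution; the expected
  share of each logarithmic size class is the exact integral of
  ``dp**delta`` across the class (not a midpoint evaluation), so recovery
  tests isolate estimator bias from discretisation bias.  Counts are
  multinomial draws scaled to a target total abundance, with a single
  multiplicative lognormal counting-error factor (CV = 20 % by default,
  matching the conservative microscopy error convention).
* Time series decline exponentially in abundance from a post-seeding peak
  while the spectral slope drifts linearly in log-time, emulating the
  observed shift toward relatively more small particles as large
  aggregates settle out.
* Trap compositions are built by mixing dust analog (Al 4.12 %, calcite
  30 %) with organic matter so that the POC-to-dry-weight ratio hits a
  target (1.5 % by default), then inverting to the measured quantities
  (%TC, %Ca, %Al, Al mass), optionally with multiplicative lognormal
  measurement noise.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .size_spectrum import SizeClassGrid, TEPSample
from .trap_budget import DustAnalogSpec, MinicosmConfig, TrapSample

__all__ = [
    "TEPSimParams",
    "TimeSeriesParams",
    "TrapSimParams",
    "power_law_class_probabilities",
    "simulate_tep_counts",
    "simulate_timeseries",
    "simulate_trap",
]

# CaCO3 stoichiometry (g mol-1)
_M_CACO3 = 100.0
_M_CA = 40.0
_M_C = 12.0


@dataclass(frozen=True)
class TEPSimParams:
    """Parameters of one simulated TEP count table.

    ``total_abundance`` (# mL-1) sets the multinomial size; ``delta`` the
    generating spectral slope (realistic spectra have delta < 0, from about
    -1.7 just after a dust deposition to about -3.3 at the end of an
    experiment); ``counting_cv`` the relative SD of the lognormal counting
    factor.  ``k`` is the implied power-law normalisation and is derived,
    not set.
    """

    delta: float
    total_abundance: float
    counting_cv: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_abundance < 0:
            raise ValueError("total_abundance must be >= 0")
        if self.counting_cv < 0:
            raise ValueError("counting_cv must be >= 0")

    def k(self, grid: SizeClassGrid) -> float:
        """Power-law normalisation implied by the target abundance."""
        integrals = _class_integrals(self.delta, grid)
        return self.total_abundance / float(integrals.sum())


@dataclass(frozen=True)
class TimeSeriesParams:
    """Shape of a simulated post-seeding TEP time series.

    Abundance follows ``peak_abundance * exp(-decline_rate * t)`` and the
    generating slope interpolates linearly in log-time between
    ``delta_start`` and ``delta_end`` over the sampling schedule (hours
    after seeding).  Defaults mirror a typical minicosm schedule and the
    observed drift of the spectrum toward small particles.
    """

    sampling_hours: tuple[float, ...] = (1, 6, 12, 24, 48, 72, 96, 144)
    peak_abundance: float = 14000.0
    decline_rate: float = 0.008  # h-1; ~14000 -> ~4400 over 144 h
    delta_start: float = -2.0
    delta_end: float = -3.2
    counting_cv: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        hours = tuple(float(h) for h in self.sampling_hours)
        if len(hours) < 1 or any(h <= 0 for h in hours):
            raise ValueError("sampling_hours must be positive (hours after seeding)")
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ValueError("sampling_hours must be strictly increasing")
        object.__setattr__(self, "sampling_hours", hours)
        if self.peak_abundance < 0 or self.counting_cv < 0:
            raise ValueError("peak_abundance and counting_cv must be >= 0")


@dataclass(frozen=True)
class TrapSimParams:
    """Mixing recipe for a simulated sediment-trap composition.

    ``dust_fraction_exported`` is the fraction of the added dust that
    reaches the trap (0.31-0.74 across published minicosm runs);
    ``poc_to_dry_ratio_percent`` the organic-carbon content of the trapped
    material (1.5 +/- 0.1 % across those runs); ``organic_c_fraction`` the
    carbon content of the organic matter itself; ``measurement_cv`` the
    relative SD of the lognormal noise applied to each measured quantity.
    """

    dust_fraction_exported: float
    poc_to_dry_ratio_percent: float = 1.5
    dust_calcite_fraction: float = 0.30
    organic_c_fraction: float = 0.5
    measurement_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dust_fraction_exported <= 1):
            raise ValueError("dust_fraction_exported must lie in [0, 1]")
        if not (0 <= self.dust_calcite_fraction <= 1):
            raise ValueError("dust_calcite_fraction must lie in [0, 1]")
        if not (0 < self.organic_c_fraction <= 1):
            raise ValueError("organic_c_fraction must lie in (0, 1]")
        if self.poc_to_dry_ratio_percent < 0 or self.measurement_cv < 0:
            raise ValueError("ratio and measurement_cv must be >= 0")
        if self.poc_to_dry_ratio_percent / 100.0 >= self.organic_c_fraction:
            raise ValueError(
                "poc_to_dry_ratio must be below the organic-matter carbon "
                "fraction; no mixture can reach it otherwise"
            )


def _class_integrals(delta: float, grid: SizeClassGrid) -> np.ndarray:
    """Exact integral of dp**delta over each size class."""
    lo, hi = grid.boundaries[:-1], grid.boundaries[1:]
    if delta == -1.0:
        return np.log(hi / lo)
    e = delta + 1.0
    return (hi**e - lo**e) / e


def power_law_class_probabilities(delta: float, grid: SizeClassGrid) -> np.ndarray:
    """Expected share of each size class under dN/d(dp) proportional to dp**delta."""
    integrals = _class_integrals(delta, grid)
    return integrals / integrals.sum()


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Unit-mean multiplicative lognormal factor with relative SD ``cv``."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_tep_counts(
    params: TEPSimParams,
    grid: SizeClassGrid,
    rng: np.random.Generator | None = None,
    label: str = "sim",
    hours_post_seeding: float | None = None,
) -> TEPSample:
    """Draw one TEP count table from a power-law spectrum.

    Counts are multinomial over the exact class integrals, then scaled by a
    single unit-mean lognormal factor emulating the enumeration error on
    the whole sample.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    p = power_law_class_probabilities(params.delta, grid)
    n = int(round(params.total_abundance))
    counts = rng.multinomial(n, p).astype(float)
    counts *= _lognormal_factor(rng, params.counting_cv)
    return TEPSample(
        counts=counts,
        label=label,
        hours_post_seeding=hours_post_seeding,
        counting_error_fraction=params.counting_cv,
    )


def simulate_timeseries(
    params: TimeSeriesParams, grid: SizeClassGrid
) -> list[TEPSample]:
    """Simulate a declining post-seeding TEP time series.

    Returns one sample per entry of ``sampling_hours``; abundance is
    maximal at the first sample and the generating slope drifts from
    ``delta_start`` to ``delta_end`` linearly in log-time.
    """
    rng = np.random.default_rng(params.seed)
    hours = np.asarray(params.sampling_hours, dtype=float)
    logt = np.log(hours)
    if logt[-1] > logt[0]:
        frac = (logt - logt[0]) / (logt[-1] - logt[0])
    else:
        frac = np.zeros_like(logt)
    deltas = params.delta_start + frac * (params.delta_end - params.delta_start)
    samples = []
    for t, d in zip(hours, deltas):
        abundance = params.peak_abundance * np.exp(-params.decline_rate * t)
        p = TEPSimParams(
            delta=float(d),
            total_abundance=float(abundance),
            counting_cv=params.counting_cv,
            seed=params.seed,
        )
        samples.append(
            simulate_tep_counts(
                p, grid, rng=rng, label=f"T{t:g}", hours_post_seeding=float(t)
            )
        )
    return samples


def simulate_trap(
    params: TrapSimParams,
    dust: DustAnalogSpec = DustAnalogSpec(),
    config: MinicosmConfig = MinicosmConfig(),
    label: str = "sim-trap",
) -> TrapSample:
    """Simulate one trap composition by mixing dust analog and organic matter.

    The construction inverts the budget stoichiometry exactly: with
    ``measurement_cv = 0`` running the result through ``full_budget``
    recovers the generating dust fraction and POC ratio to machine
    precision.
    """
    rng = np.random.default_rng(params.seed)
    dust_mass = params.dust_fraction_exported * dust.mass_added_mg
    r = params.poc_to_dry_ratio_percent / 100.0
    c_org = params.organic_c_fraction
    # dry = dust + organic, poc = c_org * organic, poc/dry = r
    organic_mass = r * dust_mass / (c_org - r)
    dry_mass = dust_mass + organic_mass
    if dry_mass == 0:
        return TrapSample(
            label=label, tc_percent=0.0, ca_percent=0.0, al_percent=0.0,
            al_mass_mg=0.0, dry_mass_mg=0.0,
        )
    al_mass = dust.al_fraction * dust_mass
    calcite_mass = params.dust_calcite_fraction * dust_mass
    ca_mass = calcite_mass * _M_CA / _M_CACO3
    pic_mass = calcite_mass * _M_C / _M_CACO3
    poc_mass = c_org * organic_mass
    tc = 100.0 * (pic_mass + poc_mass) / dry_mass
    ca = 100.0 * ca_mass / dry_mass
    al = 100.0 * al_mass / dry_mass
    if params.measurement_cv > 0:
        noise = _lognormal_factor(rng, params.measurement_cv, size=4)
        tc, ca, al, al_mass = (v * f for v, f in zip((tc, ca, al, al_mass), noise))
    return TrapSample(
        label=label,
        tc_percent=float(tc),
        ca_percent=float(ca),
        al_percent=float(al),
        al_mass_mg=float(al_mass),
        dry_mass_mg=None if params.measurement_cv > 0 else float(dry_mass),
    )
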