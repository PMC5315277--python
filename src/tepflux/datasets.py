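"""Published CHIPIE minicosm trap measurements and derived reference values.

The CHIPIE experiments are three dust-seeding minicosm runs (spring,
autumn, winter; one non-acidified "NA" and one acidified "A" tank each)
whose sediment-trap compositions and derived budgets were published in
tabular form.  The packaged CSV carries, per trap:

* the measured inputs — POC weight % of the dry material, Al weight %,
  and Al mass (mg) recovered in the trap;
* the published derived cells (``*_published`` columns) — POC stocks,
  POC fluxes, % dust exported and lithogenic fluxes — used only to verify
  that this package's budget chain reproduces them.

Raw microscopy count tables and trap dry masses were not published; the
:mod:`tepflux.synthetic` generators stand in for those.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ballast import FluxPoint
from .trap_budget import DustAnalogSpec, MinicosmConfig, TrapSample

__all__ = [
    "load_chipie_traps",
    "chipie_trap_samples",
    "chipie_flux_points",
    "CHIPIE_DUST",
    "CHIPIE_CONFIG",
    "PUBLISHED_BALLAST_SLOPE",
    "PUBLISHED_BALLAST_R2",
    "PUBLISHED_MEAN_POC_TO_DRY_PERCENT",
    "EVENT_DUST_FLUX_G_M2",
    "EVENT_POC_LITHO_G_M2",
    "EVENT_TOTAL_POC_G_M2",
    "EVENT_CONTRIBUTION_PERCENT",
    "ANNUAL_DUST_FLUX_G_M2_YR",
    "ANNUAL_POC_FLUX_G_M2_YR",
    "ANNUAL_CONTRIBUTION_PERCENT",
    "DUNE_VALIDATION_POINTS",
]

# Experiment configuration shared by all CHIPIE runs
CHIPIE_DUST = DustAnalogSpec()  # Al 4.12 %, 3.6 g added, 10 g m-2
CHIPIE_CONFIG = MinicosmConfig()  # 0.36 m2, 6 days

# Published summary statistics of the ballast regression and extrapolations
PUBLISHED_BALLAST_SLOPE = 0.012  # 3 d.p.
PUBLISHED_BALLAST_R2 = 0.985  # 3 d.p., centered convention
PUBLISHED_MEAN_POC_TO_DRY_PERCENT = 1.5  # +/- 0.1 across the six traps

# Event-scale extrapolation: extreme Saharan deposition, February 2004
EVENT_DUST_FLUX_G_M2 = 22.0
EVENT_POC_LITHO_G_M2 = 0.27
EVENT_TOTAL_POC_G_M2 = 0.8
EVENT_CONTRIBUTION_PERCENT = 34.0

# Annual-scale extrapolation (NW Mediterranean climatology)
ANNUAL_DUST_FLUX_G_M2_YR = 11.4
ANNUAL_POC_FLUX_G_M2_YR = 2.4
ANNUAL_CONTRIBUTION_PERCENT = 6.0  # approximate

# In-situ mesocosm (DUNE R1/R2) fluxes used as out-of-sample validation:
# (lithogenic mg m-2 over 6 d, POC_litho mg m-2 over 6 d)
DUNE_VALIDATION_POINTS = (("DUNE-R1", 3342.0, 31.0), ("DUNE-R2", 2139.0, 23.0))


def load_chipie_traps() -> pd.DataFrame:
    """Load the packaged CHIPIE trap table as a DataFrame."""
    with resources.files("tepflux.data").joinpath("chipie_minicosms.csv").open() as fh:
        return pd.read_csv(fh)


def chipie_trap_samples() -> list[TrapSample]:
    """The six trap samples built from the published measured inputs.

    %Ca was not published per trap; the published POC % already has the
    carbonate carbon removed, so the samples are encoded with
    ``ca_percent = 0`` and ``tc_percent`` equal to the published POC %.
    """
    df = load_chipie_traps()
    return [
        TrapSample(
            label=row.label,
            tc_percent=row.poc_percent,
            ca_percent=0.0,
            al_percent=row.al_percent,
            al_mass_mg=row.al_mass_mg,
        )
        for row in df.itertuples()
    ]


def chipie_flux_points(
    dust: DustAnalogSpec = CHIPIE_DUST, config: MinicosmConfig = CHIPIE_CONFIG
) -> list[FluxPoint]:
    """The six daily flux pairs underlying the ballast regression.

    Daily POC flux is the published POC stock over area and duration; daily
    lithogenic flux is the published Al mass through the Al proxy over area
    and duration.
    """
    df = load_chipie_traps()
    denom = config.surface_area_m2 * config.duration_days
    return [
        FluxPoint(
            label=row.label,
            litho_flux_daily=row.al_mass_mg / dust.al_fraction / denom,
            poc_flux_daily=row.poc_stock_mg_published / denom,
        )
        for row in df.itertuples()
    ]
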