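"""Sediment-trap elemental mass budgets for dust-seeding minicosms.

The particulate material that settles into a minicosm's bottom trap over an
experiment is freeze-dried and analysed for total carbon (%TC, elemental
analyser), calcium and aluminium (%Ca, %Al, ICP-AES).  Under two standard
assumptions these three numbers close the carbon and lithogenic budgets:

* all particulate calcium is calcium carbonate, so the particulate
  inorganic carbon fraction is %PIC = %Ca * 12/40 (molar masses of C and
  Ca) and %POC = %TC - %PIC;
* aluminium only enters the trap with the dust, so the lithogenic (dust)
  mass is the measured Al mass divided by the Al mass fraction of the dust
  analog (4.12 +/- 0.39 % for the aged <20 um Saharan soil fraction used in
  these experiments).

Fluxes are stocks divided by the minicosm surface area (0.36 m2), daily
fluxes additionally by the experiment duration (6 days).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "BudgetError",
    "DustAnalogSpec",
    "MinicosmConfig",
    "TrapSample",
    "BudgetResult",
    "pic_percent",
    "poc_percent",
    "poc_flux",
    "dust_recovery",
    "lithogenic_flux",
    "full_budget",
]

CARBON_MOLAR_MASS = 12.0  # g mol-1
CALCIUM_MOLAR_MASS = 40.0  # g mol-1


class BudgetError(ValueError):
    """Infeasible composition or configuration for a trap budget."""


@dataclass(frozen=True)
class DustAnalogSpec:
    """Composition and dosing of the dust analog.

    Defaults describe the chemically aged <20 um Saharan soil fraction:
    Al mass fraction 4.12 % (SD 0.39 %), 3.6 g sprayed per minicosm,
    equivalent to a 10 g m-2 deposition event.
    """

    al_fraction: float = 0.0412
    al_fraction_sd: float = 0.0039
    mass_added_mg: float = 3600.0
    flux_applied_g_m2: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.al_fraction < 1):
            raise BudgetError("al_fraction must lie in (0, 1)")
        if self.mass_added_mg <= 0:
            raise BudgetError("mass_added_mg must be > 0")


@dataclass(frozen=True)
class MinicosmConfig:
    """Geometry and duration of one minicosm experiment."""

    surface_area_m2: float = 0.36
    duration_days: float = 6.0

    def __post_init__(self) -> None:
        if self.surface_area_m2 <= 0 or self.duration_days <= 0:
            raise BudgetError("surface area and duration must be > 0")


@dataclass(frozen=True)
class TrapSample:
    """Elemental composition of one sediment-trap sample (dry-mass basis).

    ``dry_mass_mg`` is optional; when absent it is inferred from the Al
    measurements as ``al_mass_mg / al_percent * 100`` (the only closure the
    %/mass pairs permit when the total dry mass was not recorded).
    """

    label: str
    tc_percent: float
    ca_percent: float
    al_percent: float
    al_mass_mg: float
    dry_mass_mg: float | None = None

    def __post_init__(self) -> None:
        for name in ("tc_percent", "ca_percent", "al_percent"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise BudgetError(f"{name}={v} outside [0, 100]")
        if self.al_mass_mg < 0:
            raise BudgetError("al_mass_mg must be >= 0")
        if self.dry_mass_mg is not None and self.al_mass_mg > self.dry_mass_mg:
            raise BudgetError("Al mass cannot exceed dry mass")

    def inferred_dry_mass_mg(self) -> float:
        if self.dry_mass_mg is not None:
            return self.dry_mass_mg
        if self.al_percent == 0:
            if self.al_mass_mg == 0:
                return 0.0
            raise BudgetError("cannot infer dry mass: al_percent is 0 but al_mass > 0")
        return self.al_mass_mg / self.al_percent * 100.0


@dataclass(frozen=True)
class BudgetResult:
    """Derived carbon and lithogenic budget for one trap."""

    label: str
    pic_percent: float
    poc_percent: float
    dry_mass_mg: float
    poc_stock_mg: float
    poc_stock_mmol: float
    poc_flux_total: float  # mg m-2 over the experiment
    poc_flux_daily: float  # mg m-2 d-1
    dust_recovered_mg: float
    dust_exported_percent: float
    litho_flux_total: float  # mg m-2 over the experiment
    litho_flux_daily: float  # mg m-2 d-1


def pic_percent(ca_percent: float) -> float:
    """Particulate inorganic carbon as weight %, assuming all Ca is CaCO3."""
    if not (0 <= ca_percent <= 100):
        raise BudgetError(f"ca_percent={ca_percent} outside [0, 100]")
    return ca_percent * CARBON_MOLAR_MASS / CALCIUM_MOLAR_MASS


def poc_percent(tc_percent: float, ca_percent: float) -> float:
    """Particulate organic carbon as weight %: %TC minus carbonate carbon."""
    pic = pic_percent(ca_percent)
    if tc_percent < pic:
        raise BudgetError(
            f"PIC ({pic:.2f}%) exceeds TC ({tc_percent:.2f}%): "
            "the all-Ca-as-calcite assumption is violated"
        )
    return tc_percent - pic


def poc_flux(
    poc_stock_mg: float, config: MinicosmConfig = MinicosmConfig()
) -> tuple[float, float, float]:
    """POC export flux from the trapped carbon stock.

    Returns ``(total mg m-2, daily mg m-2 d-1, stock mmol C)``.
    """
    if poc_stock_mg < 0:
        raise BudgetError("poc_stock_mg must be >= 0")
    total = poc_stock_mg / config.surface_area_m2
    return total, total / config.duration_days, poc_stock_mg / CARBON_MOLAR_MASS


def dust_recovery(
    al_mass_mg: float, dust: DustAnalogSpec = DustAnalogSpec()
) -> tuple[float, float]:
    """Dust mass recovered in the trap (mg) and % of the added dust, via Al.

    A recovery slightly above 100 % is within the Al-fraction uncertainty
    and triggers a warning; larger excesses raise.
    """
    if al_mass_mg < 0:
        raise BudgetError("al_mass_mg must be >= 0")
    recovered = al_mass_mg / dust.al_fraction
    percent = 100.0 * recovered / dust.mass_added_mg
    if percent > 100.0:
        # tolerance implied by the +/- SD on the analog's Al fraction
        limit = 100.0 * dust.al_fraction / max(dust.al_fraction - dust.al_fraction_sd, 1e-12)
        if percent <= limit:
            warnings.warn(
                f"dust recovery {percent:.1f}% exceeds 100% but is within the "
                "Al-fraction uncertainty",
                stacklevel=2,
            )
        else:
            raise BudgetError(
                f"dust recovery {percent:.1f}% exceeds 100% beyond the "
                "Al-fraction uncertainty"
            )
    return recovered, percent


def lithogenic_flux(
    al_mass_mg: float,
    dust: DustAnalogSpec = DustAnalogSpec(),
    config: MinicosmConfig = MinicosmConfig(),
) -> tuple[float, float]:
    """Lithogenic particle flux (total mg m-2, daily mg m-2 d-1) from Al mass."""
    recovered, _ = dust_recovery(al_mass_mg, dust)
    total = recovered / config.surface_area_m2
    return total, total / config.duration_days


def full_budget(
    trap: TrapSample,
    dust: DustAnalogSpec = DustAnalogSpec(),
    config: MinicosmConfig = MinicosmConfig(),
) -> BudgetResult:
    """Complete carbon + lithogenic budget for one trap sample.

    Warns when the Al-implied lithogenic mass exceeds the trap dry mass —
    an internal inconsistency that can arise from partial calcite
    dissolution altering the composition between dosing and collection.
    """
    pic = pic_percent(trap.ca_percent)
    poc = poc_percent(trap.tc_percent, trap.ca_percent)
    dry_mass = trap.inferred_dry_mass_mg()
    poc_stock = poc * dry_mass / 100.0
    total_poc, daily_poc, stock_mmol = poc_flux(poc_stock, config)
    recovered, exported_pct = dust_recovery(trap.al_mass_mg, dust)
    total_litho, daily_litho = lithogenic_flux(trap.al_mass_mg, dust, config)
    if recovered > dry_mass > 0:
        warnings.warn(
            f"{trap.label or 'trap'}: Al-implied lithogenic mass "
            f"({recovered:.0f} mg) exceeds the trap dry mass ({dry_mass:.0f} mg); "
            "compositions are internally inconsistent (possible calcite "
            "dissolution)",
            stacklevel=2,
        )
    return BudgetResult(
        label=trap.label,
        pic_percent=pic,
        poc_percent=poc,
        dry_mass_mg=dry_mass,
        poc_stock_mg=poc_stock,
        poc_stock_mmol=stock_mmol,
        poc_flux_total=total_poc,
        poc_flux_daily=daily_poc,
        dust_recovered_mg=recovered,
        dust_exported_percent=exported_pct,
        litho_flux_total=total_litho,
        litho_flux_daily=daily_litho,
    )
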