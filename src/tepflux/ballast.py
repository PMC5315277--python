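"""Lithogenic-ballast regression: POC export vs lithogenic flux.

Across dust-seeded minicosms the POC flux to the sediment trap is
proportional to the lithogenic (dust) flux, consistent with mineral
ballasting of organic-mineral aggregates.  The relationship is summarised
by a zero-intercept least-squares line

    F_POClitho = a * F_litho

whose slope ``a`` (mg POC per mg lithogenic material) can then be applied
to observed dust deposition events to estimate the ballast-driven POC
export they induce.

Conventions
-----------
slope
    Closed form a = sum(x*y) / sum(x**2), the exact least-squares solution
    with no intercept.
r_squared
    Centered convention: 1 - RSS / sum((y - mean(y))**2) with RSS taken
    from the origin fit.  For a through-origin fit this can in principle be
    negative; it is the convention that matches how these regressions are
    reported in the field.
p_value
    Two-sided t-test on the slope of the one-parameter regression, with
    n - 1 degrees of freedom and slope SE = sqrt(RSS/(n-1) / sum(x**2)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BallastFitError",
    "FluxPoint",
    "BallastFit",
    "fit_through_origin",
    "predict_poc_litho",
    "contribution_fraction",
]


class BallastFitError(ValueError):
    """Degenerate input to the through-origin regression."""


@dataclass(frozen=True)
class FluxPoint:
    """One minicosm's paired daily fluxes (mg m-2 d-1)."""

    label: str
    litho_flux_daily: float
    poc_flux_daily: float

    def __post_init__(self) -> None:
        if self.litho_flux_daily < 0 or self.poc_flux_daily < 0:
            raise BallastFitError("fluxes must be >= 0")


@dataclass(frozen=True)
class BallastFit:
    """Zero-intercept fit of POC flux on lithogenic flux."""

    slope: float
    r_squared: float
    p_value: float
    n_points: int
    residuals: np.ndarray
    labels: tuple[str, ...] = ()

    def predict(self, litho_flux: float) -> float:
        return predict_poc_litho(self, litho_flux)


def fit_through_origin(points: Iterable[FluxPoint] | Sequence[FluxPoint]) -> BallastFit:
    """Least-squares fit of ``y = a*x`` over paired flux points.

    The slope is scale-free in time basis: fitting daily fluxes or fluxes
    integrated over the whole experiment gives the same slope and r2 as
    long as both axes share the basis.
    """
    pts = list(points)
    if len(pts) < 2:
        raise BallastFitError("need at least 2 flux points")
    x = np.array([p.litho_flux_daily for p in pts], dtype=float)
    y = np.array([p.poc_flux_daily for p in pts], dtype=float)
    sxx = float((x * x).sum())
    if sxx == 0:
        raise BallastFitError("all lithogenic fluxes are zero; slope undefined")
    slope = float((x * y).sum() / sxx)
    resid = y - slope * x
    rss = float((resid**2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    if tss > 0:
        r2 = 1.0 - rss / tss
    else:
        r2 = 1.0 if np.isclose(rss, 0.0) else 0.0
    n = len(pts)
    if rss <= 0:
        p_value = 0.0
    else:
        se = np.sqrt(rss / (n - 1) / sxx)
        t = slope / se
        p_value = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return BallastFit(
        slope=slope,
        r_squared=r2,
        p_value=p_value,
        n_points=n,
        residuals=resid,
        labels=tuple(p.label for p in pts),
    )


def predict_poc_litho(fit: BallastFit | float, litho_flux: float) -> float:
    """Ballast-associated POC flux predicted for a given lithogenic flux.

    Units follow the input: feed a daily flux to get a daily flux, an
    event-integrated flux to get an event-integrated flux.
    """
    if litho_flux < 0:
        raise BallastFitError("litho_flux must be >= 0")
    slope = fit.slope if isinstance(fit, BallastFit) else float(fit)
    return slope * litho_flux


def contribution_fraction(poc_litho: float, total_poc: float) -> float:
    """Percentage of a total POC export attributable to lithogenic ballast."""
    if total_poc <= 0:
        raise BallastFitError("total_poc must be > 0")
    return 100.0 * poc_litho / total_poc
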