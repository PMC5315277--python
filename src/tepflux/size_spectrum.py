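"""Number-size-distribution statistics for transparent exopolymer particles (TEP).

Microscopy enumeration of alcian-blue-stainable gel particles yields, per
water sample, a count of particles per mL in each of a set of logarithmic
diameter classes (by default 15 classes spanning 1-135 um).  This module
turns such count tables into the four summary statistics used throughout
dust-seeding minicosm studies:

* the width-normalised number size distribution dN/d(dp)  (# mL-1 um-1),
* the spectral slope delta of the power law  dN/d(dp) = k * dp**delta,
* the abundance-weighted average diameter D_av (um),
* the spherical-equivalent volume concentration C_v (ppm, v/v).

A more negative spectral slope means relatively more small particles.  The
fit is an unweighted ordinary least squares in log10 space over the classes
with strictly positive counts; empty classes carry no information about the
density and are excluded rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = [
    "GridError",
    "SpectrumFitError",
    "SizeClassGrid",
    "TEPSample",
    "SpectrumFit",
    "build_log_size_classes",
    "normalized_distribution",
    "fit_spectral_slope",
    "average_diameter",
    "volume_concentration",
    "abundance_with_error",
]

MidpointKind = Literal["arithmetic", "geometric"]


class GridError(ValueError):
    """Invalid size-class grid specification."""


class SpectrumFitError(ValueError):
    """Size-spectrum statistic is undefined for the given counts."""


@dataclass(frozen=True)
class SizeClassGrid:
    """Logarithmic diameter classes for particle sizing.

    Parameters
    ----------
    boundaries
        ``n_classes + 1`` strictly increasing class-boundary diameters (um).
    midpoint_kind
        Convention for the representative diameter ``dp_i`` of each class:
        ``"arithmetic"`` (mean of the boundaries, the default) or
        ``"geometric"`` (sqrt of their product, sometimes preferred for
        logarithmic binning).
    """

    boundaries: np.ndarray
    midpoint_kind: MidpointKind = "arithmetic"

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise GridError("grid needs at least two boundaries")
        if not np.all(np.isfinite(b)) or b[0] <= 0:
            raise GridError("boundaries must be finite and positive")
        if not np.all(np.diff(b) > 0):
            raise GridError("boundaries must be strictly increasing")
        if self.midpoint_kind not in ("arithmetic", "geometric"):
            raise GridError(f"unknown midpoint convention {self.midpoint_kind!r}")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_classes(self) -> int:
        return self.boundaries.size - 1

    @property
    def d_min(self) -> float:
        return float(self.boundaries[0])

    @property
    def d_max(self) -> float:
        return float(self.boundaries[-1])

    @property
    def midpoints(self) -> np.ndarray:
        """Representative diameter dp_i of each class (um)."""
        lo, hi = self.boundaries[:-1], self.boundaries[1:]
        if self.midpoint_kind == "geometric":
            return np.sqrt(lo * hi)
        return 0.5 * (lo + hi)

    @property
    def widths(self) -> np.ndarray:
        """Class width d(dp) (um)."""
        return np.diff(self.boundaries)

    def with_midpoint_kind(self, kind: MidpointKind) -> "SizeClassGrid":
        return replace(self, midpoint_kind=kind)


def build_log_size_classes(
    d_min: float = 1.0,
    d_max: float = 135.0,
    n_classes: int = 15,
    midpoint_kind: MidpointKind = "arithmetic",
) -> SizeClassGrid:
    """Build ``n_classes`` logarithmic size classes between ``d_min`` and ``d_max``.

    Boundaries follow a geometric progression with common ratio
    ``(d_max/d_min)**(1/n_classes)``, so every class has the same width on a
    log axis.  Defaults give the 15 classes spanning 1-135 um used for TEP
    sizing at x200/x400 magnification.
    """
    if not (0 < d_min < d_max):
        raise GridError(f"need 0 < d_min < d_max, got ({d_min}, {d_max})")
    if n_classes < 1:
        raise GridError("n_classes must be >= 1")
    # exact endpoints; geometric spacing in between
    edges = d_min * (d_max / d_min) ** (np.arange(n_classes + 1) / n_classes)
    edges[0], edges[-1] = d_min, d_max
    return SizeClassGrid(boundaries=edges, midpoint_kind=midpoint_kind)


@dataclass(frozen=True)
class TEPSample:
    """Per-class TEP counts for one water sample.

    ``counts[i]`` is the TEP concentration (# mL-1) in size class *i* of the
    associated grid.  ``hours_post_seeding`` is ``None`` for pre-seeding
    controls (conventionally labelled C1/C2).  ``counting_error_fraction``
    is the relative counting uncertainty applied to the total abundance;
    microscopy counting errors span roughly 3-20 % and the conservative
    upper end (0.20) is the default.
    """

    counts: np.ndarray
    label: str = ""
    hours_post_seeding: float | None = None
    counting_error_fraction: float = 0.20

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 1:
            raise ValueError("counts must be a 1-D array")
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValueError("counts must be finite and non-negative")
        if self.counting_error_fraction < 0:
            raise ValueError("counting_error_fraction must be >= 0")
        object.__setattr__(self, "counts", c)

    @property
    def abundance(self) -> float:
        """Total TEP abundance [TEP] (# mL-1)."""
        return float(self.counts.sum())


@dataclass(frozen=True)
class SpectrumFit:
    """Fitted power law dN/d(dp) = k * dp**delta.

    ``delta`` is the (dimensionless) spectral slope, ``k`` the normalisation
    (# mL-1 um-1 at dp = 1 um), ``n_bins_used`` how many positive-count
    classes entered the log-log fit, and ``r_squared`` the ordinary
    coefficient of determination of that fit.
    """

    delta: float
    k: float
    n_bins_used: int
    r_squared: float


def _check_shape(sample: TEPSample, grid: SizeClassGrid) -> None:
    if sample.counts.size != grid.n_classes:
        raise ValueError(
            f"sample has {sample.counts.size} classes, grid has {grid.n_classes}"
        )


def normalized_distribution(sample: TEPSample, grid: SizeClassGrid) -> np.ndarray:
    """Width-normalised number size distribution dN/d(dp) (# mL-1 um-1)."""
    _check_shape(sample, grid)
    return sample.counts / grid.widths


def fit_spectral_slope(sample: TEPSample, grid: SizeClassGrid) -> SpectrumFit:
    """Fit the spectral slope by log-log ordinary least squares.

    Only classes with strictly positive counts enter the fit; at least two
    are required.  The regression is ``log10 dN/d(dp) = log10 k +
    delta * log10 dp`` with dp the class representative diameter.
    """
    _check_shape(sample, grid)
    dens = normalized_distribution(sample, grid)
    pos = dens > 0
    n_used = int(pos.sum())
    if n_used < 2:
        raise SpectrumFitError(
            f"power-law fit needs >= 2 positive size classes, got {n_used}"
        )
    x = np.log10(grid.midpoints[pos])
    y = np.log10(dens[pos])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 1.0
    return SpectrumFit(
        delta=float(slope), k=float(10.0**intercept), n_bins_used=n_used, r_squared=r2
    )


def average_diameter(sample: TEPSample, grid: SizeClassGrid) -> float:
    """Abundance-weighted average diameter D_av (um).

    D_av = sum_i N(dp_i) * dp_i / sum_i N(dp_i).
    """
    _check_shape(sample, grid)
    total = sample.abundance
    if total <= 0:
        raise SpectrumFitError("average diameter undefined for all-zero counts")
    return float((sample.counts * grid.midpoints).sum() / total)


def volume_concentration(sample: TEPSample, grid: SizeClassGrid) -> float:
    """Spherical-equivalent volume concentration C_v (ppm, v/v).

    C_v = sum_i (pi/6) dp_i**3 N(dp_i) * 1e-6 with dp_i in um and N in
    # mL-1 (1 um3 mL-1 = 1e-12 v/v, so the 1e-6 factor yields ppm).
    """
    _check_shape(sample, grid)
    return float((np.pi / 6.0 * grid.midpoints**3 * sample.counts).sum() * 1e-6)


def abundance_with_error(sample: TEPSample) -> tuple[float, float]:
    """Total abundance and its counting-error standard deviation (# mL-1).

    The SD is ``counting_error_fraction`` times the total abundance — the
    conservative flat relative error convention used for microscopy counts.
    """
    total = sample.abundance
    return total, sample.counting_error_fraction * total
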