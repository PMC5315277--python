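"""Run configuration: plain key-value (YAML) config files and defaults.

A config file is flat ``key: value`` text.  Recognised keys (all optional;
defaults are the standard minicosm experiment values):

    d_min_um: 1.0            # size grid lower bound
    d_max_um: 135.0          # size grid upper bound
    n_classes: 15
    midpoint_kind: arithmetic   # or geometric
    counting_error_fraction: 0.20
    surface_area_m2: 0.36
    duration_days: 6
    dust_al_fraction: 0.0412
    dust_al_fraction_sd: 0.0039
    dust_mass_added_mg: 3600
    seed: 0
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .size_spectrum import SizeClassGrid, build_log_size_classes
from .trap_budget import DustAnalogSpec, MinicosmConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Grid, minicosm and dust-analog parameters for one pipeline run."""

    d_min_um: float = 1.0
    d_max_um: float = 135.0
    n_classes: int = 15
    midpoint_kind: str = "arithmetic"
    counting_error_fraction: float = 0.20
    surface_area_m2: float = 0.36
    duration_days: float = 6.0
    dust_al_fraction: float = 0.0412
    dust_al_fraction_sd: float = 0.0039
    dust_mass_added_mg: float = 3600.0
    seed: int = 0

    def grid(self) -> SizeClassGrid:
        return build_log_size_classes(
            self.d_min_um, self.d_max_um, self.n_classes, self.midpoint_kind
        )

    def minicosm(self) -> MinicosmConfig:
        return MinicosmConfig(self.surface_area_m2, self.duration_days)

    def dust(self) -> DustAnalogSpec:
        return DustAnalogSpec(
            al_fraction=self.dust_al_fraction,
            al_fraction_sd=self.dust_al_fraction_sd,
            mass_added_mg=self.dust_mass_added_mg,
        )

    def sha256(self) -> str:
        """Stable hash of the full parameter set, for output provenance."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from a flat key-value YAML file (or defaults)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain key: value pairs")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
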