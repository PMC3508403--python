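"""Run configuration: every tunable of the pipeline in one validated place.

Defaults mirror the incubation conditions the pipeline was designed
around: 200/100 µmol l⁻¹ ¹⁵NH₄⁺/¹⁴NO₂⁻ in slurry
Experiment 1, 200 µmol l⁻¹ ¹⁵NO₃⁻ in Experiment 2, 50 µmol l⁻¹ ¹⁵NO₃⁻ in
core overlying water, and integration to the 2 cm nitrate penetration
depth.  A run writes its resolved configuration next to its outputs so
results are reproducible from the report bundle alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .isotope_signals import AIR_R29, AIR_R30
from .watercolumn import AREA_BASIN_NORTH6N_M2, AREA_OMZ_BENTHIC_M2, MOLAR_MASS_N

_RANGES = {
    "alpha": (0.0, 1.0),
    "porosity": (0.0, 1.0),
    "bulk_density": (0.0, 10.0),
    "integration_depth_cm": (0.0, 100.0),
    "air_r29": (0.0, 0.1),
    "air_r30": (0.0, 0.1),
    "n28_conc": (0.0, 5000.0),
    "added_15nh4": (0.0, 1e5),
    "added_14no2": (0.0, 1e5),
    "added_15no3": (0.0, 1e5),
    "overlying_15no3": (0.0, 1e5),
    "ambient_14nh4": (0.0, 1e5),
    "porewater_14no3": (0.0, 1e5),
    "bottomwater_14no3": (0.0, 1e5),
    "area_omz_benthic_m2": (0.0, 1e15),
    "area_basin_north6n_m2": (0.0, 1e15),
    "days_per_year": (1.0, 366.0),
    "molar_mass_n": (10.0, 20.0),
    "delay_resid_threshold": (0.0, 100.0),
    "delay_slope_se_threshold": (0.0, 100.0),
}


@dataclass
class RunConfig:
    """Validated pipeline configuration; see module docstring for defaults."""

    alpha: float = 0.05
    porosity: float = 0.8
    bulk_density: float = 1.0
    integration_depth_cm: float = 2.0
    air_r29: float = AIR_R29
    air_r30: float = AIR_R30
    n28_conc: float = 500.0
    added_15nh4: float = 200.0
    added_14no2: float = 100.0
    added_15no3: float = 200.0
    overlying_15no3: float = 50.0
    ambient_14nh4: float = 10.0
    porewater_14no3: float = 20.0
    bottomwater_14no3: float = 30.0
    area_omz_benthic_m2: float = AREA_OMZ_BENTHIC_M2
    area_basin_north6n_m2: float = AREA_BASIN_NORTH6N_M2
    days_per_year: float = 365.0
    molar_mass_n: float = MOLAR_MASS_N
    delay_resid_threshold: float = 2.0
    delay_slope_se_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not (lo < v <= hi) and not (name.startswith("added") and v == 0):
                raise ConfigurationError(
                    f"config field {name} = {v} outside ({lo}, {hi}]"
                )
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")

    @property
    def f_nh4_nominal(self) -> float:
        """Nominal ¹⁵NH₄⁺ labeling fraction for Experiment 1."""
        return self.added_15nh4 / (self.added_15nh4 + self.ambient_14nh4)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )
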