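"""Water-column nitrogen deficit (N*) and basin-scale N-loss budgets.

N* measures the deviation of fixed nitrogen from Redfield stoichiometry
relative to phosphate; strongly negative values in oxygen minimum zone
waters indicate net fixed-N removal.  Areal benthic or pelagic rates are
extrapolated to annual basin losses in Tg N yr⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from .errors import InputError, MissingFieldError

#: Seafloor area in contact with O2 < 22 µmol l⁻¹ water (m²).
AREA_OMZ_BENTHIC_M2 = 1.15e12

#: Basin area north of 6°N (m²), used for pelagic extrapolations.
AREA_BASIN_NORTH6N_M2 = 4.93e12

#: Molar mass of nitrogen (g mol⁻¹).
MOLAR_MASS_N = 14.007


@dataclass
class NutrientSample:
    """One depth of a nutrient/oxygen profile (concentrations in µmol l⁻¹)."""

    depth_m: float
    nh4: float | None = None
    no2: float | None = None
    no3: float | None = None
    po4: float | None = None
    o2: float | None = None
    station_id: str = ""

    def __post_init__(self):
        if self.depth_m < 0:
            raise InputError(f"depth must be >= 0, got {self.depth_m}")
        for name in ("nh4", "no2", "no3", "po4", "o2"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise InputError(f"{name} must be finite and >= 0, got {v}")


def nstar(sample: NutrientSample) -> float:
    """Fixed-nitrogen deficit N* = [NH₄⁺]+[NO₂⁻]+[NO₃⁻]−16·[PO₄³⁻]+2.9.

    The 16:1 N:P ratio is Redfield stoichiometry; the +2.9 µmol l⁻¹ offset
    centres the global mean ocean at zero.  Result in µmol N l⁻¹; negative
    values mark a nitrogen deficit.
    """
    for name in ("nh4", "no2", "no3", "po4"):
        if getattr(sample, name) is None:
            raise MissingFieldError(f"nstar requires {name}; it is absent")
    return sample.nh4 + sample.no2 + sample.no3 - 16.0 * sample.po4 + 2.9


def annual_basin_nloss(
    areal_rate: float,
    area_m2: float,
    days_per_year: float = 365.0,
    molar_mass: float = MOLAR_MASS_N,
) -> float:
    """Scale an areal N-loss rate to an annual basin-wide loss.

    Parameters
    ----------
    areal_rate : float
        mmol N m⁻² d⁻¹.
    area_m2 : float
        Extrapolation area in m².

    Returns
    -------
    float
        Tg N yr⁻¹ = rate·10⁻³ mol · molar_mass g/mol · days · area · 10⁻¹² Tg/g.
        Bilinear in rate and area.
    """
    if areal_rate < 0 or area_m2 <= 0 or days_per_year <= 0 or molar_mass <= 0:
        raise InputError("annual_basin_nloss inputs must be positive")
    return areal_rate * 1e-3 * molar_mass * days_per_year * area_m2 * 1e-12
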