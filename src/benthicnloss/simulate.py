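"""Forward simulation of ¹⁵N-labeling incubations with known true rates.

The simulator generates isotope-ratio time series with the same schema as
real measurements, so every inference stage can be tested by parameter
recovery.  It encodes the incubation conditions the inference chain is
designed for:

* Slurry Experiment 1 — ¹⁵NH₄⁺ (200 µmol l⁻¹) + ¹⁴NO₂⁻ (100 µmol l⁻¹) with
  ATU inhibiting aerobic ammonia oxidation: anammox is the only ²⁹N₂
  source, no ³⁰N₂ is produced.
* Slurry Experiment 2 — ¹⁵NO₃⁻ (200 µmol l⁻¹) added to dissolved ¹⁴NO₃⁻
  pools, optionally with intracellular ¹⁴NO₃⁻ released when the slurry is
  mixed at t = 0 (nitrate-storing organisms such as foraminifera): the
  effective labeling fraction is diluted below the nominal one.
* Intact cores — ¹⁵NO₃⁻ at 50 µmol l⁻¹ in the overlying water, five time
  points over 15 h, sacrificial triplicate cores per time point.

Production is zero-order (linear accumulation) over the incubation —
matching the linear-slope analysis; substrate depletion is not modeled
because tracer amendments are large relative to consumption.  Measurement
noise is multiplicative Gaussian on the isotope ratios, reflecting the
error structure of isotope-ratio mass spectrometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .isotope_signals import (
    AIR_R29,
    AIR_R30,
    IncubationSeries,
    aqueous_slope_from_volumetric,
)

#: Intact-core geometry: subsampled liner diameter (cm), overlying water
#: height (cm) and the sediment depth mixed into the overlying water when a
#: core is sacrificed.
CORE_DIAMETER_CM = 3.6
CORE_WATER_HEIGHT_CM = 12.5
CORE_MIXED_SEDIMENT_CM = 6.0


def core_geometry(
    diameter_cm: float = CORE_DIAMETER_CM,
    water_height_cm: float = CORE_WATER_HEIGHT_CM,
    mixed_sediment_cm: float = CORE_MIXED_SEDIMENT_CM,
    porosity: float = 0.8,
) -> tuple[float, float]:
    """Return (area_m2, mixed_volume_l) of a core incubation.

    The mixed volume is the overlying water plus the pore water of the
    sediment interval homogenized into it at sampling.
    """
    area_cm2 = math.pi * (diameter_cm / 2.0) ** 2
    volume_l = area_cm2 * (water_height_cm + porosity * mixed_sediment_cm) / 1000.0
    return area_cm2 * 1e-4, volume_l


def areal_rate_core(
    slope: float,
    porosity: float = 0.8,
    atoms: bool = False,
) -> float:
    """Convert a core-slurry production slope (µmol N₂ l⁻¹ h⁻¹) to an areal
    rate (µmol m⁻² d⁻¹; N₂ by default, N atoms with ``atoms=True``)."""
    area_m2, volume_l = core_geometry(porosity=porosity)
    f = 2.0 if atoms else 1.0
    return slope * 24.0 * f * volume_l / area_m2


@dataclass
class SlurryScenario:
    """True rates and conditions of one simulated slurry incubation.

    Rates are in nmol N₂ cm⁻³ sediment d⁻¹; concentrations in µmol l⁻¹
    (final, in the mixed slurry) except the intracellular store, which is
    per cm³ of sediment and released into the pore water when the slurry is
    mixed at t = 0.
    """

    true_D: float
    true_A: float
    seed: int
    added_15nh4: float = 200.0
    added_14no2: float = 100.0
    added_15no3: float = 200.0
    ambient_14nh4: float = 10.0
    porewater_14no3: float = 20.0
    bottomwater_14no3: float = 30.0
    intracellular_14no3: float = 0.0  # nmol (cm3 sediment)^-1
    gradual_release_h: float = 0.0  # 0 = instantaneous release at t=0
    n_timepoints: int = 6
    duration_h: float = 27.0
    noise_sd_ratio: float = 0.0
    volume_sediment_cm3: float = 160.0
    volume_water_ml: float = 200.0
    porosity: float = 0.8
    n28_conc: float = 500.0
    station_id: str = "sim"
    layer: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self):
        if self.true_D < 0 or self.true_A < 0:
            raise InputError("true rates must be >= 0")
        for name in (
            "added_15nh4", "added_14no2", "added_15no3", "ambient_14nh4",
            "porewater_14no3", "bottomwater_14no3", "intracellular_14no3",
        ):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.n_timepoints < 5:
            raise InputError("need at least 5 time points")
        if self.seed is None:
            raise InputError("seed must be set explicitly")

    # -- derived truth, used by tests and the inversion oracle ------------

    @property
    def water_volume_l(self) -> float:
        return self.volume_water_ml / 1000.0 + self.porosity * self.volume_sediment_cm3 / 1000.0

    @property
    def slurry_to_sediment(self) -> float:
        """µmol l⁻¹ (aqueous) → nmol (cm³ sediment)⁻¹ conversion factor."""
        return 1e3 * self.water_volume_l / self.volume_sediment_cm3

    @property
    def f_nh4(self) -> float:
        """Nominal ammonium labeling fraction (Experiment 1)."""
        return self.added_15nh4 / (self.added_15nh4 + self.ambient_14nh4)

    @property
    def dissolved_14no3(self) -> float:
        """Mixed dissolved ¹⁴NO₃⁻ (µmol l⁻¹) from bottom water and pore water."""
        v_bw = self.volume_water_ml / 1000.0
        v_pw = self.porosity * self.volume_sediment_cm3 / 1000.0
        v = self.water_volume_l
        return (self.bottomwater_14no3 * v_bw + self.porewater_14no3 * v_pw) / v

    @property
    def f_no3_nominal(self) -> float:
        """Labeling fraction from tracer + dissolved pools only."""
        return self.added_15no3 / (self.added_15no3 + self.dissolved_14no3)

    @property
    def released_14no3_aqueous(self) -> float:
        """Fully released intracellular store as an aqueous concentration."""
        return self.intracellular_14no3 / self.slurry_to_sediment

    @property
    def f_no3_true(self) -> float:
        """Effective labeling fraction after full intracellular release."""
        c14 = self.dissolved_14no3 + self.released_14no3_aqueous
        return self.added_15no3 / (self.added_15no3 + c14)


@dataclass
class CoreScenario:
    """True rates of one simulated intact-core incubation.

    ``true_D14`` and ``true_D15`` are the unlabeled- and labeled-fueled
    denitrification components (µmol N₂ m⁻² d⁻¹); their ratio fixes the
    effective ¹⁵N fraction of the reduction-zone nitrate pool,
    f = D15/(D14+D15).  ``true_A`` is anammox N₂ production, which draws one
    atom from that pool and one from (unlabeled) ammonium.
    """

    true_D14: float
    true_D15: float
    true_A: float
    seed: int
    overlying_15no3: float = 50.0
    n_timepoints: int = 5
    duration_h: float = 15.0
    n_replicates: int = 3
    noise_sd_ratio: float = 0.0
    porosity: float = 0.8
    n28_conc: float = 500.0
    station_id: str = "sim"

    def __post_init__(self):
        if min(self.true_D14, self.true_D15, self.true_A) < 0:
            raise InputError("true rates must be >= 0")
        if self.true_D15 == 0 and (self.true_D14 > 0 or self.true_A > 0):
            raise InputError(
                "true_D15 must be > 0 when any production occurs: without "
                "labeled denitrification no 30N2 signal exists to pair against"
            )
        if self.n_timepoints < 4:
            raise InputError("need at least 4 time points")

    @property
    def f_reduction_zone(self) -> float:
        """¹⁵N fraction of the nitrate pool in the reduction zone."""
        d = self.true_D14 + self.true_D15
        return self.true_D15 / d if d > 0 else 0.0

    @property
    def true_total_n2(self) -> float:
        """Total true N-loss, D14 + D15 + A, in µmol N₂ m⁻² d⁻¹."""
        return self.true_D14 + self.true_D15 + self.true_A

    @property
    def ra(self) -> float:
        return self.true_A / (self.true_A + self.true_D14 + self.true_D15)

    @property
    def expected_p29_p30(self) -> tuple[float, float]:
        """Noise-free areal production rates (µmol N₂ m⁻² d⁻¹)."""
        f = self.f_reduction_zone
        d = self.true_D14 + self.true_D15
        p30 = f * f * d
        p29 = 2.0 * f * (1.0 - f) * d + f * self.true_A
        return p29, p30


def _ratio_series(
    times: np.ndarray,
    slope29: float,
    slope30: float,
    n28: float,
    noise_sd: float,
    rng: np.random.Generator,
    released29_0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Air baseline plus linear excess, with multiplicative ratio noise."""
    excess29 = slope29 * times + released29_0
    excess30 = slope30 * times
    r29 = AIR_R29 + excess29 / n28
    r30 = AIR_R30 + excess30 / n28
    if noise_sd > 0:
        r29 = r29 * (1.0 + noise_sd * rng.standard_normal(times.shape))
        r30 = r30 * (1.0 + noise_sd * rng.standard_normal(times.shape))
    return np.maximum(r29, 1e-12), np.maximum(r30, 1e-12)


def _slurry_series(
    scn: SlurryScenario, experiment: str, p29_vol: float, p30_vol: float
) -> IncubationSeries:
    times = np.linspace(0.0, scn.duration_h, scn.n_timepoints)
    dummy = IncubationSeries(
        sample_id="_geom", experiment=experiment, station_id=scn.station_id,
        time_h=times[:4], r29=np.full(4, AIR_R29), r30=np.full(4, AIR_R30),
        n28_conc=scn.n28_conc, layer=scn.layer,
        volume_sediment_cm3=scn.volume_sediment_cm3,
        volume_water_ml=scn.volume_water_ml,
    )
    slope29 = aqueous_slope_from_volumetric(p29_vol, dummy, scn.porosity, atoms=False)
    slope30 = aqueous_slope_from_volumetric(p30_vol, dummy, scn.porosity, atoms=False)
    rng = np.random.default_rng(scn.seed)
    r29, r30 = _ratio_series(
        times, slope29, slope30, scn.n28_conc, scn.noise_sd_ratio, rng
    )
    return IncubationSeries(
        sample_id=f"{scn.station_id}-{experiment}-{scn.layer[0]:g}-{scn.layer[1]:g}",
        experiment=experiment,
        station_id=scn.station_id,
        time_h=times,
        r29=r29,
        r30=r30,
        n28_conc=scn.n28_conc,
        layer=scn.layer,
        volume_sediment_cm3=scn.volume_sediment_cm3,
        volume_water_ml=scn.volume_water_ml,
    )


def simulate_slurry_ex1(scn: SlurryScenario) -> IncubationSeries:
    """Experiment 1: ¹⁵NH₄⁺ + ¹⁴NO₂⁻ with nitrification inhibited.

    Anammox pairs labeled ammonium with unlabeled nitrite, producing ²⁹N₂
    at A·F(NH₄⁺); denitrification of the unlabeled NOₓ pool adds only ²⁸N₂,
    so p³⁰ = 0.
    """
    p29 = scn.true_A * scn.f_nh4
    return _slurry_series(scn, "slurry_ex1", p29, 0.0)


def simulate_slurry_ex2(scn: SlurryScenario) -> IncubationSeries:
    """Experiment 2: ¹⁵NO₃⁻ over dissolved and (optionally) intracellular
    ¹⁴NO₃⁻ pools.

    With effective labeling fraction F (after release of any stored
    ¹⁴NO₃⁻), denitrification produces ³⁰N₂ at D·F² and ²⁹N₂ at 2F(1−F)·D;
    anammox adds ²⁹N₂ at A·F.  With ``gradual_release_h > 0`` the store
    enters the pool linearly over that interval instead of at t = 0 and the
    cumulative curves are integrated numerically.
    """
    if scn.gradual_release_h <= 0:
        f = scn.f_no3_true
        p30 = scn.true_D * f * f
        p29 = 2.0 * f * (1.0 - f) * scn.true_D + scn.true_A * f
        return _slurry_series(scn, "slurry_ex2", p29, p30)

    # gradual release: time-varying F(t), integrate instantaneous production
    times = np.linspace(0.0, scn.duration_h, scn.n_timepoints)
    fine = np.linspace(0.0, scn.duration_h, 2001)
    released = np.minimum(fine / scn.gradual_release_h, 1.0) * scn.released_14no3_aqueous
    c14 = scn.dissolved_14no3 + released
    f_t = scn.added_15no3 / (scn.added_15no3 + c14)
    inst29 = 2.0 * f_t * (1.0 - f_t) * scn.true_D + scn.true_A * f_t
    inst30 = scn.true_D * f_t * f_t
    dummy = _slurry_series(scn, "slurry_ex2", 0.0, 0.0)
    # cumulative aqueous excess (µmol/l) at the sampling times
    from scipy.integrate import cumulative_trapezoid

    # nmol N2 (cm3 sed)^-1 accumulated by each time (rates are per day)
    cum29 = cumulative_trapezoid(inst29, fine, initial=0.0) / 24.0
    cum30 = cumulative_trapezoid(inst30, fine, initial=0.0) / 24.0
    # amount per cm3 sediment -> aqueous concentration µmol l^-1
    exc29 = np.interp(times, fine, cum29) / scn.slurry_to_sediment
    exc30 = np.interp(times, fine, cum30) / scn.slurry_to_sediment
    rng = np.random.default_rng(scn.seed)
    r29 = AIR_R29 + exc29 / scn.n28_conc
    r30 = AIR_R30 + exc30 / scn.n28_conc
    if scn.noise_sd_ratio > 0:
        r29 = r29 * (1.0 + scn.noise_sd_ratio * rng.standard_normal(times.shape))
        r30 = r30 * (1.0 + scn.noise_sd_ratio * rng.standard_normal(times.shape))
    dummy.sample_id = f"{scn.station_id}-slurry_ex2-{scn.layer[0]:g}-{scn.layer[1]:g}"
    dummy.time_h, dummy.r29, dummy.r30 = times, np.maximum(r29, 1e-12), np.maximum(r30, 1e-12)
    return dummy


def simulate_core(scn: CoreScenario) -> IncubationSeries:
    """Intact-core incubation: ¹⁵NO₃⁻ in the overlying water, sacrificial
    replicate cores per time point (replicates repeat the sampling time).

    The core is treated as well mixed with a single effective
    reduction-zone labeling fraction — the same assumption the rIPT
    inversion makes — so the simulator tests the inference, not sediment
    diffusion physics.
    """
    p29_areal, p30_areal = scn.expected_p29_p30
    area_m2, volume_l = core_geometry(porosity=scn.porosity)
    to_conc = area_m2 / (volume_l * 24.0)  # µmol m⁻² d⁻¹ → µmol l⁻¹ h⁻¹
    base = np.linspace(0.0, scn.duration_h, scn.n_timepoints)
    times = np.repeat(base, max(1, scn.n_replicates))
    rng = np.random.default_rng(scn.seed)
    r29, r30 = _ratio_series(
        times, p29_areal * to_conc, p30_areal * to_conc,
        scn.n28_conc, scn.noise_sd_ratio, rng,
    )
    return IncubationSeries(
        sample_id=f"{scn.station_id}-core",
        experiment="core",
        station_id=scn.station_id,
        time_h=times,
        r29=r29,
        r30=r30,
        n28_conc=scn.n28_conc,
    )
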