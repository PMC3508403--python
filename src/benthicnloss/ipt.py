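"""Isotope-pairing algebra: partitioning N₂ production into anammox and
denitrification, labeling-fraction inversion, excess intracellular nitrate,
and the revised isotope pairing technique (rIPT) for intact cores.

Background
----------
After addition of a ¹⁵N-labeled substrate, the isotopologue composition of
produced N₂ identifies the pathway.  Denitrification draws both N atoms of
an N₂ from the same NOₓ pool with ¹⁵N mole fraction F, producing
²⁸/²⁹/³⁰N₂ binomially as (1−F)², 2F(1−F), F².  Anammox combines one
NOₓ-derived atom with one ammonium-derived atom, so with ¹⁵NO₃⁻ labeling it
produces at most ²⁹N₂ (never ³⁰N₂), and with ¹⁵NH₄⁺ labeling at fraction F
it produces ²⁹N₂ at A·F.

Two slurry experiments constrain the partitioning:

* Experiment 1 (¹⁵NH₄⁺ + ¹⁴NO₂⁻, nitrification inhibited): anammox is the
  only ²⁹N₂ source, so A = p²⁹/F(NH₄⁺).
* Experiment 2 (¹⁵NO₃⁻): denitrification is the only ³⁰N₂ source, so
  D = p³⁰/F(NO₃⁻)²; anammox is recovered after subtracting the
  denitrification-derived ²⁹N₂.

When sediments host nitrate-storing organisms (foraminifera, large sulfur
bacteria), unlabeled intracellular ¹⁴NO₃⁻ released during slurry mixing
dilutes the nominal labeling fraction.  The effective fraction F* is then
inverted from the pairing equations under the constraint that both
experiments see the same anammox rate, and the implied extra ¹⁴NO₃⁻ is
reported as excess nitrate per cm³ of sediment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateRatioError,
    DivisionDomainError,
    InfeasibleInversionError,
    InputError,
    UndefinedFractionError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabelingFraction:
    """A ¹⁵N mole fraction of a substrate pool, nominal or inferred.

    ``value`` must lie in (0, 1]; ``substrate`` is "NH4" or "NO3";
    ``source`` records whether the fraction came from the tracer addition
    ("nominal") or from the pairing inversion ("inferred").
    """

    value: float
    substrate: str = "NO3"
    source: str = "nominal"

    def __post_init__(self):
        if not (0 < self.value <= 1):
            raise InputError(
                f"labeling fraction must lie in (0, 1], got {self.value}"
            )
        if self.substrate not in ("NH4", "NO3"):
            raise InputError(f"substrate must be NH4 or NO3, got {self.substrate!r}")
        if self.source not in ("nominal", "inferred"):
            raise InputError(f"source must be nominal or inferred, got {self.source!r}")


def _fraction_value(f: "LabelingFraction | float") -> float:
    v = f.value if isinstance(f, LabelingFraction) else float(f)
    if v == 0:
        raise DivisionDomainError("labeling fraction of 0 is outside the domain")
    if not (0 < v <= 1):
        raise InputError(f"labeling fraction must lie in (0, 1], got {v}")
    return v


@dataclass
class PairingObservation:
    """Production rates of ²⁹N₂ and ³⁰N₂ for one sample.

    Units are tagged: "nmol_n2_cm3_d" for slurry volumetric rates,
    "umol_n2_m2_d" for core areal rates.  A channel rejected by the slope
    filter is recorded as ``None`` (absent), never as zero.
    """

    p29: float | None
    p30: float | None
    units_tag: str = "nmol_n2_cm3_d"

    def __post_init__(self):
        if self.units_tag not in ("nmol_n2_cm3_d", "umol_n2_m2_d"):
            raise InputError(f"unknown units_tag {self.units_tag!r}")
        for name, v in (("p29", self.p29), ("p30", self.p30)):
            if v is not None and (not math.isfinite(v) or v < 0):
                raise InputError(f"{name} must be finite and >= 0 when present, got {v}")


@dataclass
class SlurryRates:
    """Partitioned slurry rates for one sediment layer (N₂ units internally)."""

    station_id: str
    layer: tuple[float, float]
    A_ex1: float | None
    D_ex2: float | None
    A_ex2: float | None
    F_star: LabelingFraction | None
    excess_no3: float | None  # nmol 14NO3- (cm3 sediment)^-1
    flagged: list[str] = field(default_factory=list)


@dataclass
class CoreNLoss:
    """Partitioned areal N-loss for one intact-core station (N-atom units,
    mmol N m⁻² d⁻¹)."""

    station_id: str
    ra: float
    R29: float
    nloss_total: float
    denit: float
    anammox: float


def anammox_ex1(p29: float, f_nh4: LabelingFraction | float) -> float:
    """Total anammox N₂ production from Experiment 1: A = p²⁹ / F(NH₄⁺).

    With nitrification inhibited and no ¹⁵NO₃⁻ present, every ²⁹N₂ carries
    exactly one labeled ammonium-derived atom, so production scales with the
    ammonium labeling fraction.
    """
    if p29 < 0:
        raise InputError(f"p29 must be >= 0, got {p29}")
    return p29 / _fraction_value(f_nh4)


def denit_ex2(p30: float, f_no3: LabelingFraction | float) -> float:
    """Total denitrification N₂ production from Experiment 2: D = p³⁰ / F²."""
    if p30 < 0:
        raise InputError(f"p30 must be >= 0, got {p30}")
    return p30 / _fraction_value(f_no3) ** 2


def anammox_ex2(
    p29: float,
    p30: float,
    f_no3: LabelingFraction | float,
    clamp_negative: bool = True,
) -> float:
    """Anammox N₂ production from Experiment 2 after removing the
    denitrification-derived ²⁹N₂:

        A = (p²⁹ − 2·((1−F)/F)·p³⁰) / F

    Noise-driven negative results are floored at 0 and logged (the physical
    rate is non-negative); pass ``clamp_negative=False`` to obtain the raw
    value for diagnostics.
    """
    if p29 < 0 or p30 < 0:
        raise InputError("p29 and p30 must be >= 0")
    f = _fraction_value(f_no3)
    a = (p29 - 2.0 * ((1.0 - f) / f) * p30) / f
    if a < 0 and clamp_negative:
        logger.warning(
            "anammox_ex2: negative rate %.4g floored at 0 (p29=%.4g, p30=%.4g, F=%.4g)",
            a, p29, p30, f,
        )
        return 0.0
    return a


def infer_fstar(
    p29: float,
    p30: float,
    a_target: float,
    f_nominal: LabelingFraction | float | None = None,
    tol: float = 1e-9,
) -> LabelingFraction:
    """Invert the effective nitrate labeling fraction F* from Experiment 2.

    Solves anammox_ex2(p29, p30, F*) = a_target for F* in (0, 1], i.e. the
    quadratic  A·F² − (p²⁹ + 2·p³⁰)·F + 2·p³⁰ = 0.  For a_target = 0 the
    equation degenerates to the linear solution F = 2p³⁰/(p²⁹ + 2p³⁰).

    Among admissible real roots the one closest to the nominal tracer
    fraction is preferred when ``f_nominal`` is given, else the larger root.

    Raises
    ------
    InfeasibleInversionError
        If no real root lies in (0, 1]; carries the discriminant.
    """
    if min(p29, p30, a_target) < 0:
        raise InputError("p29, p30 and a_target must be >= 0")
    if p29 == 0 and p30 == 0 and a_target == 0:
        raise InputError("cannot invert a labeling fraction from all-zero rates")
    b = p29 + 2.0 * p30
    if a_target == 0:
        if b == 0:
            raise InfeasibleInversionError("no production to match A = 0", None)
        root = 2.0 * p30 / b
        if not (0 < root <= 1 + tol):
            raise InfeasibleInversionError(
                f"linear solution F = {root:.4g} outside (0, 1]", None
            )
        return LabelingFraction(min(root, 1.0), substrate="NO3", source="inferred")
    disc = b * b - 8.0 * a_target * p30
    if disc < 0:
        raise InfeasibleInversionError(
            f"discriminant {disc:.4g} < 0: observed pairing cannot yield "
            f"anammox rate {a_target:.4g}",
            disc,
        )
    sq = math.sqrt(disc)
    roots = [(b - sq) / (2.0 * a_target), (b + sq) / (2.0 * a_target)]
    admissible = [r for r in roots if tol < r <= 1 + tol]
    if not admissible:
        raise InfeasibleInversionError(
            f"no root in (0, 1] (roots {roots[0]:.4g}, {roots[1]:.4g})", disc
        )
    if f_nominal is not None:
        fn = _fraction_value(f_nominal)
        root = min(admissible, key=lambda r: abs(r - fn))
    else:
        root = max(admissible)
    return LabelingFraction(min(root, 1.0), substrate="NO3", source="inferred")


def excess_nitrate(
    conc15_no3: float,
    f_star: LabelingFraction | float,
    f_nominal: LabelingFraction | float,
    slurry_to_sediment: float,
) -> float:
    """Excess unlabeled nitrate implied by labeling-fraction dilution.

        excess (aqueous, µmol l⁻¹) = [¹⁵NO₃⁻] · (1/F* − 1/F_nominal)

    converted to nmol ¹⁴NO₃⁻ per cm³ sediment by ``slurry_to_sediment``
    (= 10³ · V_water_l / V_sediment_cm³ for a slurry).  F* > F_nominal can
    only arise from noise; such values are floored at 0 with a warning.
    """
    if conc15_no3 < 0:
        raise InputError("conc15_no3 must be >= 0")
    if slurry_to_sediment <= 0:
        raise InputError("slurry_to_sediment must be > 0")
    fs = _fraction_value(f_star)
    fn = _fraction_value(f_nominal)
    aqueous = conc15_no3 * (1.0 / fs - 1.0 / fn)
    if aqueous < 0:
        logger.warning(
            "excess_nitrate: F* (%.4g) exceeds nominal F (%.4g); floored at 0",
            fs, fn,
        )
        return 0.0
    return aqueous * slurry_to_sediment


def anammox_fraction(a: float, d: float) -> float:
    """Contribution of anammox to total N₂ production, ra = A/(A+D).

    Scale-invariant: any common rescaling of A and D leaves ra unchanged.
    """
    if a < 0 or d < 0:
        raise InputError("rates must be >= 0")
    if a + d == 0:
        raise UndefinedFractionError("anammox fraction undefined for A = D = 0")
    return a / (a + d)


def ript_nloss(obs: PairingObservation, ra: float) -> CoreNLoss:
    """Total benthic N-loss from an intact-core incubation by the revised
    isotope pairing technique.

    With ¹⁵NO₃⁻ added to the overlying water, the nitrate pool in the
    reduction zone attains an (unknown) ¹⁵N fraction f.  Using the anammox
    contribution ra estimated independently (here from slurry incubations)
    and the measured production ratio R²⁹ = p²⁹/p³⁰, the unlabeled-to-
    labeled ratio of that pool is

        r₁₄ = (1−f)/f = [(1−ra)·R²⁹ − ra] / (2 − ra)

    from which denitrification D = p³⁰/f² = p³⁰·(1+r₁₄)² and anammox
    A = D·ra/(1−ra).  The reported total is in N atoms:

        N-loss = 2·(A + D) = 2·p³⁰·(1+r₁₄)² / (1−ra)

    At ra = 0 this reduces exactly to the classical isotope-pairing total
    D¹⁵ + D¹⁴ = (p²⁹ + 2p³⁰)·(1 + p²⁹/(2p³⁰)).

    Parameters
    ----------
    obs : PairingObservation
        Core areal production rates (µmol N₂ m⁻² d⁻¹); the result is in
        mmol N m⁻² d⁻¹ (atoms, ×10⁻³ from µmol).
    ra : float
        Anammox fraction of total N₂ production in [0, 1).
    """
    if obs.p29 is None or obs.p30 is None:
        raise InputError("both isotopologue channels are required for rIPT")
    if obs.p30 <= 0:
        raise DegenerateRatioError("p30 must be > 0: R29 undefined")
    if not (0 <= ra < 1):
        raise InputError(f"ra must lie in [0, 1), got {ra}")
    r29 = obs.p29 / obs.p30
    r14 = ((1.0 - ra) * r29 - ra) / (2.0 - ra)
    if r14 < 0:
        # f > 1 implied: observed 29/30 ratio lower than anammox-free pairing
        # can explain for this ra. Clamp to a fully labeled pool.
        logger.warning(
            "ript_nloss: implied unlabeled ratio %.4g < 0 (R29=%.4g, ra=%.4g); "
            "clamping to fully labeled pool", r14, r29, ra,
        )
        r14 = 0.0
    d_n2 = obs.p30 * (1.0 + r14) ** 2
    a_n2 = d_n2 * ra / (1.0 - ra)
    total_atoms = 2.0 * (a_n2 + d_n2)
    labeled_atoms = obs.p29 + 2.0 * obs.p30
    if total_atoms < labeled_atoms - 1e-9 * max(1.0, labeled_atoms):
        logger.warning(
            "ript_nloss: implied total %.4g below observed labeled production %.4g",
            total_atoms, labeled_atoms,
        )
    scale = 1e-3  # µmol -> mmol
    total = total_atoms * scale
    return CoreNLoss(
        station_id="",
        ra=ra,
        R29=r29,
        nloss_total=total,
        denit=(1.0 - ra) * total,
        anammox=ra * total,
    )


def depth_integrate(
    layer_rates: Sequence[tuple[float, float, float]],
    integration_depth_cm: float = 2.0,
) -> float:
    """Integrate volumetric rates over sediment depth to an areal flux.

    Parameters
    ----------
    layer_rates
        Sequence of (top_cm, bottom_cm, rate) with rates in
        nmol N cm⁻³ d⁻¹ and non-overlapping layers.
    integration_depth_cm
        Lower bound of the integral (the nitrate penetration depth);
        layers are clipped to it.

    Returns
    -------
    float
        Areal rate in mmol N m⁻² d⁻¹
        (nmol cm⁻³ · cm · 10⁴ cm² m⁻² · 10⁻⁶ mmol nmol⁻¹ = ×10⁻²).

    A layer with an absent (rejected) rate should simply be omitted by the
    caller; it then contributes zero, a conservative integral.
    """
    if integration_depth_cm <= 0:
        raise InputError("integration depth must be > 0")
    layers = sorted(layer_rates, key=lambda lr: lr[0])
    prev_bottom = -np.inf
    total = 0.0
    deepest = 0.0
    for top, bottom, rate in layers:
        if bottom <= top:
            raise InputError(f"layer ({top}, {bottom}) has non-positive thickness")
        if top < prev_bottom - 1e-12:
            raise InputError("layers overlap")
        prev_bottom = bottom
        deepest = max(deepest, bottom)
        thickness = max(0.0, min(bottom, integration_depth_cm) - max(top, 0.0))
        total += rate * thickness
    if integration_depth_cm > deepest + 1e-12:
        logger.warning(
            "depth_integrate: integration depth %.3g cm exceeds deepest layer "
            "%.3g cm; integral is truncated (conservative)",
            integration_depth_cm, deepest,
        )
    return total * 1e-2
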