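"""From raw N₂ isotope-ratio time series to filtered production slopes.

Incubation subsamples are measured as ²⁹N₂/²⁸N₂ and ³⁰N₂/²⁸N₂ mole ratios.
This module converts those ratios to excess concentrations relative to the
air-equilibrium isotope baseline, estimates linear production rates by
ordinary least squares, and applies the acceptance filter used throughout
the pipeline: only production with a significant linear slope (p < alpha)
over time and without an initial delay enters any rate calculation.

The air baseline is computed from the atmospheric ¹⁵N atom fraction under
binomial isotope pairing and can be overridden with locally calibrated air
standards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateDesignError,
    InputError,
    InsufficientDataError,
)

#: Atom fraction of ¹⁵N in atmospheric N₂.
AIR_15N_FRACTION = 0.0036765

#: Air-equilibrium ²⁹N₂/²⁸N₂ mole ratio, 2x(1-x)/(1-x)² with x the ¹⁵N atom
#: fraction — binomial pairing of atmospheric nitrogen.
AIR_R29 = 2 * AIR_15N_FRACTION / (1 - AIR_15N_FRACTION)

#: Air-equilibrium ³⁰N₂/²⁸N₂ mole ratio, x²/(1-x)².
AIR_R30 = (AIR_15N_FRACTION / (1 - AIR_15N_FRACTION)) ** 2

VALID_EXPERIMENTS = ("slurry_ex1", "slurry_ex2", "core")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional")
    return arr


@dataclass
class IncubationSeries:
    """One incubation's isotope-ratio time series plus tracer/volume metadata.

    Parameters
    ----------
    sample_id : str
        Identifier of the incubation (bag or core set).
    experiment : {"slurry_ex1", "slurry_ex2", "core"}
        Which labeling experiment produced the series.
    station_id : str
        Station the sediment came from.
    layer : tuple of (top_cm, bottom_cm) or None
        Sediment depth interval for slurries; ``None`` for intact cores.
    time_h : array-like
        Sampling times in hours, non-negative and non-decreasing (replicate
        exetainers at a time point may repeat a time).
    r29, r30 : array-like
        ²⁹N₂/²⁸N₂ and ³⁰N₂/²⁸N₂ mole ratios per subsample, all > 0.
    n28_conc : float or array-like
        ²⁸N₂ concentration in µmol l⁻¹, a single reference value or one per
        time point.  ²⁸N₂ is effectively constant relative to tracer excess.
    volume_sediment_cm3, volume_water_ml : float, optional
        Slurry geometry (sediment slice volume and added degassed water);
        required for slurry experiments, unused for cores.
    """

    sample_id: str
    experiment: str
    station_id: str
    time_h: np.ndarray
    r29: np.ndarray
    r30: np.ndarray
    n28_conc: float | np.ndarray
    layer: tuple[float, float] | None = None
    volume_sediment_cm3: float | None = None
    volume_water_ml: float | None = None

    def __post_init__(self):
        if self.experiment not in VALID_EXPERIMENTS:
            raise InputError(
                f"experiment must be one of {VALID_EXPERIMENTS}, got {self.experiment!r}"
            )
        self.time_h = _as_float_array(self.time_h, "time_h")
        self.r29 = _as_float_array(self.r29, "r29")
        self.r30 = _as_float_array(self.r30, "r30")
        n = len(self.time_h)
        if len(self.r29) != n or len(self.r30) != n:
            raise InputError("time_h, r29 and r30 must have equal length")
        if n < 4:
            raise InsufficientDataError(
                f"series {self.sample_id}: {n} time points, need at least 4"
            )
        if np.any(~np.isfinite(self.time_h)) or np.any(self.time_h < 0):
            raise InputError(f"series {self.sample_id}: times must be finite and >= 0")
        if np.any(np.diff(self.time_h) < 0):
            raise InputError(f"series {self.sample_id}: times must be non-decreasing")
        for name, arr in (("r29", self.r29), ("r30", self.r30)):
            bad = np.where(~np.isfinite(arr) | (arr <= 0))[0]
            if bad.size:
                raise InputError(
                    f"series {self.sample_id}: non-finite or non-positive {name} "
                    f"at index {bad[0]}"
                )
        n28 = np.asarray(self.n28_conc, dtype=float)
        if n28.ndim == 0:
            n28 = np.full(n, float(n28))
        elif len(n28) != n:
            raise InputError("n28_conc must be scalar or match time_h length")
        bad = np.where(~np.isfinite(n28) | (n28 <= 0))[0]
        if bad.size:
            raise InputError(
                f"series {self.sample_id}: bad n28_conc at index {bad[0]}"
            )
        self.n28_conc = n28
        if self.experiment != "core":
            if not self.volume_sediment_cm3 or self.volume_sediment_cm3 <= 0:
                raise InputError("slurry series need volume_sediment_cm3 > 0")
            if not self.volume_water_ml or self.volume_water_ml <= 0:
                raise InputError("slurry series need volume_water_ml > 0")


@dataclass
class ExcessSeries:
    """Excess ²⁹N₂ and ³⁰N₂ concentrations (µmol l⁻¹) above air equilibrium."""

    time_h: np.ndarray
    excess29: np.ndarray
    excess30: np.ndarray


@dataclass
class SlopeEstimate:
    """OLS production-rate estimate with the significance/delay filter applied.

    ``accepted`` is True iff the slope is significant at ``alpha`` (two-sided
    t-test, df = n-2) and no initial delay was detected.
    """

    slope: float
    stderr: float
    p_value: float
    intercept: float
    n_points: int
    delay_detected: bool
    accepted: bool
    reason: str = ""


def excess_relative_to_air(
    series: IncubationSeries,
    air_r29: float = AIR_R29,
    air_r30: float = AIR_R30,
) -> ExcessSeries:
    """Convert ratio series to excess isotopologue concentrations.

    excess29_i = (r29_i − air_r29) · [²⁸N₂]_i and analogously for ³⁰N₂, so
    the result is linear in the ratio deviation from the air baseline.
    Excess may be slightly negative through measurement noise.
    """
    for name, val in (("air_r29", air_r29), ("air_r30", air_r30)):
        if not (0 < val < 0.1):
            raise InputError(f"{name} must lie in (0, 0.1), got {val}")
    n28 = np.asarray(series.n28_conc, dtype=float)
    excess29 = (series.r29 - air_r29) * n28
    excess30 = (series.r30 - air_r30) * n28
    return ExcessSeries(time_h=series.time_h.copy(), excess29=excess29, excess30=excess30)


def _studentized_first_residual(t: np.ndarray, y: np.ndarray, fit) -> float:
    """Externally studentized residual of the first observation of a simple
    OLS fit (leverage in closed form)."""
    n = len(t)
    resid = y - (fit.intercept + fit.slope * t)
    sxx = np.sum((t - t.mean()) ** 2)
    h = 1.0 / n + (t - t.mean()) ** 2 / sxx
    sse = float(np.sum(resid**2))
    e0, h0 = float(resid[0]), float(h[0])
    df = n - 3
    if df < 1:
        return 0.0
    s2_loo = (sse - e0**2 / (1.0 - h0)) / df
    if s2_loo <= 0:
        return np.inf if abs(e0) > 0 else 0.0
    return e0 / np.sqrt(s2_loo * (1.0 - h0))


def production_slope(
    excess: ExcessSeries | Sequence[tuple[float, float]] | tuple[np.ndarray, np.ndarray],
    channel: str = "excess29",
    alpha: float = 0.05,
    delay_resid_threshold: float = 2.0,
    delay_slope_se_threshold: float = 2.0,
) -> SlopeEstimate:
    """OLS slope of excess concentration against time, with acceptance filter.

    Parameters
    ----------
    excess
        Either an :class:`ExcessSeries` (``channel`` selects the
        isotopologue) or a sequence of (time_h, concentration) pairs.
    alpha
        Two-sided significance level of the slope t-test (default 0.05).
    delay_resid_threshold, delay_slope_se_threshold
        A delayed onset of production is declared when the first point's
        externally studentized residual exceeds ``delay_resid_threshold``,
        or when refitting without the earliest time point shifts the slope
        by more than ``delay_slope_se_threshold`` pooled standard errors.

    Notes
    -----
    Replicate observations at a shared time enter as independent points.
    The filter is deliberately conservative: a series is only used for rate
    calculations when production is linear from the start of the incubation.
    """
    if isinstance(excess, ExcessSeries):
        t = np.asarray(excess.time_h, dtype=float)
        y = np.asarray(getattr(excess, channel), dtype=float)
    else:
        pairs = np.asarray(list(excess), dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise InputError("expected a sequence of (time_h, concentration) pairs")
        t, y = pairs[:, 0], pairs[:, 1]
    if not (0 < alpha < 1):
        raise InputError(f"alpha must lie in (0, 1), got {alpha}")
    n = len(t)
    if n < 4:
        raise InsufficientDataError(f"need at least 4 points for a slope, got {n}")
    if np.ptp(t) == 0:
        raise DegenerateDesignError("zero variance in time: slope undefined")

    fit = stats.linregress(t, y)
    # linregress p-value is the two-sided t-test on the slope with df = n-2;
    # perfectly collinear data yield stderr 0 and p 0.
    p_value = float(fit.pvalue)
    significant = p_value < alpha

    delay = False
    reasons = []
    # Residuals at the floating-point rounding floor are measurement-free:
    # studentizing them would amplify pure round-off into spurious delays.
    resid = y - (fit.intercept + fit.slope * t)
    scale = max(float(np.max(np.abs(y))), float(np.ptp(y)), 1e-300)
    noiseless = float(np.sqrt(np.mean(resid**2))) <= 1e-8 * scale
    if noiseless:
        return SlopeEstimate(
            slope=float(fit.slope), stderr=float(fit.stderr), p_value=p_value,
            intercept=float(fit.intercept), n_points=n, delay_detected=False,
            accepted=significant,
            reason="" if significant else f"slope not significant (p = {p_value:.3g})",
        )
    r_stud = _studentized_first_residual(t, y, fit)
    if abs(r_stud) > delay_resid_threshold:
        delay = True
        reasons.append(
            f"first-point studentized residual {r_stud:.2f} exceeds "
            f"{delay_resid_threshold}"
        )
    first_t = t.min()
    keep = t > first_t
    if keep.sum() >= 3 and np.ptp(t[keep]) > 0:
        red = stats.linregress(t[keep], y[keep])
        pooled = float(np.hypot(fit.stderr, red.stderr))
        if pooled > 0 and abs(red.slope - fit.slope) > delay_slope_se_threshold * pooled:
            delay = True
            reasons.append(
                f"slope shift {abs(red.slope - fit.slope):.3g} exceeds "
                f"{delay_slope_se_threshold} pooled SE ({pooled:.3g})"
            )
    if not significant:
        reasons.append(f"slope not significant (p = {p_value:.3g} >= {alpha})")

    return SlopeEstimate(
        slope=float(fit.slope),
        stderr=float(fit.stderr),
        p_value=p_value,
        intercept=float(fit.intercept),
        n_points=n,
        delay_detected=delay,
        accepted=significant and not delay,
        reason="; ".join(reasons),
    )


def slurry_water_volume_l(series: IncubationSeries, porosity: float = 0.8) -> float:
    """Total aqueous slurry volume in litres: added degassed water plus pore
    water estimated as porosity × sediment volume."""
    if series.volume_water_ml is None or series.volume_sediment_cm3 is None:
        raise ConfigurationError("slurry volumes not set on series")
    if not (0 < porosity < 1):
        raise ConfigurationError(f"porosity must lie in (0, 1), got {porosity}")
    return series.volume_water_ml / 1000.0 + porosity * series.volume_sediment_cm3 / 1000.0


def volumetric_rate(
    slope: float,
    series: IncubationSeries,
    porosity: float = 0.8,
    atoms: bool = True,
) -> float:
    """Convert an aqueous N₂ production slope to a sediment volumetric rate.

    rate = slope · 24 · f · (V_water_l / V_sediment_cm³) · 10³

    with f = 2 when reporting N atoms (``atoms=True``, the published unit
    nmol N cm⁻³ d⁻¹) or f = 1 to stay in N₂ units for the pairing algebra.

    Parameters
    ----------
    slope : float
        Production slope in µmol N₂ l⁻¹ h⁻¹.
    series : IncubationSeries
        Supplies the slurry geometry.
    porosity : float
        Sediment porosity used to estimate the pore-water contribution to
        the aqueous volume.
    """
    if series.experiment == "core":
        raise ConfigurationError("volumetric_rate applies to slurry experiments only")
    v_water_l = slurry_water_volume_l(series, porosity)
    f = 2.0 if atoms else 1.0
    return slope * 24.0 * f * (v_water_l / series.volume_sediment_cm3) * 1e3


def aqueous_slope_from_volumetric(
    rate: float,
    series: IncubationSeries,
    porosity: float = 0.8,
    atoms: bool = True,
) -> float:
    """Inverse of :func:`volumetric_rate`; used by the simulator and for
    round-trip checks."""
    v_water_l = slurry_water_volume_l(series, porosity)
    f = 2.0 if atoms else 1.0
    return rate / (24.0 * f * (v_water_l / series.volume_sediment_cm3) * 1e3)
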