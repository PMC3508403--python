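"""End-to-end orchestration: series → slopes → pairing → integration →
budgets, with provenance on every output row.

The stages mirror the analysis of a ¹⁵N incubation study:

1. every series is converted to excess concentrations and each
   isotopologue channel is fitted by OLS; channels failing the
   significance/no-delay filter are logged and propagate as *absent*;
2. accepted slurry slopes become volumetric rates; Experiment 1 yields the
   anammox rate, Experiment 2 the denitrification rate after inverting the
   effective nitrate labeling fraction under A(Ex1) = A(Ex2), plus the
   excess intracellular ¹⁴NO₃⁻ implied by the dilution;
3. layer rates are integrated to areal fluxes over the nitrate penetration
   depth and give the station anammox fraction ra;
4. core incubations are evaluated with the revised isotope pairing
   technique using the station ra from the slurries;
5. optional nutrient profiles yield N*, optional qPCR tables yield gene
   fractions, and areal rates are extrapolated to annual basin N-loss.

Rates are carried in N₂ units internally and doubled to N atoms at this
reporting boundary only; all output columns carry units in their names.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import BenthicNLossError, InfeasibleInversionError
from .genes import anammox_nirs_fraction
from .ipt import (
    LabelingFraction,
    PairingObservation,
    anammox_ex1,
    anammox_ex2,
    anammox_fraction,
    denit_ex2,
    depth_integrate,
    excess_nitrate,
    infer_fstar,
    ript_nloss,
)
from .isotope_signals import (
    IncubationSeries,
    excess_relative_to_air,
    production_slope,
    slurry_water_volume_l,
    volumetric_rate,
)
from .simulate import areal_rate_core
from .watercolumn import annual_basin_nloss, nstar

logger = logging.getLogger(__name__)


def nominal_f_no3(config: RunConfig, series: IncubationSeries) -> float:
    """Nominal ¹⁵NO₃⁻ labeling fraction from tracer addition and the
    dissolved ¹⁴NO₃⁻ pools mixed into the slurry."""
    v_bw = series.volume_water_ml / 1000.0
    v_pw = config.porosity * series.volume_sediment_cm3 / 1000.0
    v = v_bw + v_pw
    dissolved = (config.bottomwater_14no3 * v_bw + config.porewater_14no3 * v_pw) / v
    return config.added_15no3 / (config.added_15no3 + dissolved)


def slope_table(series_list: list[IncubationSeries], config: RunConfig) -> pd.DataFrame:
    """One OLS slope estimate per (series, isotopologue channel)."""
    rows = []
    for s in series_list:
        excess = excess_relative_to_air(s, config.air_r29, config.air_r30)
        for channel in ("excess29", "excess30"):
            est = production_slope(
                excess,
                channel=channel,
                alpha=config.alpha,
                delay_resid_threshold=config.delay_resid_threshold,
                delay_slope_se_threshold=config.delay_slope_se_threshold,
            )
            if not est.accepted:
                logger.info(
                    "rejected %s/%s: %s", s.sample_id, channel, est.reason
                )
            rows.append({
                "sample_id": s.sample_id,
                "experiment": s.experiment,
                "station_id": s.station_id,
                "layer_top_cm": s.layer[0] if s.layer else np.nan,
                "layer_bottom_cm": s.layer[1] if s.layer else np.nan,
                "channel": "29N2" if channel == "excess29" else "30N2",
                "slope_umol_n2_l_h": est.slope,
                "stderr_umol_n2_l_h": est.stderr,
                "p_value": est.p_value,
                "intercept_umol_l": est.intercept,
                "n_points": est.n_points,
                "delay_detected": est.delay_detected,
                "accepted": est.accepted,
                "reason": est.reason,
            })
    return pd.DataFrame(rows)


def _accepted_slope(df: pd.DataFrame, sample_id: str, channel: str) -> float | None:
    sel = df[(df["sample_id"] == sample_id) & (df["channel"] == channel)]
    if sel.empty or not bool(sel["accepted"].iloc[0]):
        return None
    return max(0.0, float(sel["slope_umol_n2_l_h"].iloc[0]))


def slurry_rate_table(
    series_list: list[IncubationSeries],
    slopes: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Partitioned rates per (station, layer), N-atom units for reporting.

    For each layer, Experiment 1 provides the anammox rate; Experiment 2
    provides p²⁹/p³⁰ from which the effective labeling fraction F* is
    inverted (matching the two experiments' anammox rates), then the
    denitrification rate and the excess-nitrate store.  Absent channels
    propagate as NA with the reason flagged.
    """
    slurries = [s for s in series_list if s.experiment in ("slurry_ex1", "slurry_ex2")]
    keys = sorted({(s.station_id, s.layer) for s in slurries}, key=lambda k: (k[0], k[1]))
    rows = []
    for station, layer in keys:
        ex1 = next((s for s in slurries if s.station_id == station and s.layer == layer
                    and s.experiment == "slurry_ex1"), None)
        ex2 = next((s for s in slurries if s.station_id == station and s.layer == layer
                    and s.experiment == "slurry_ex2"), None)
        flags = []
        a_n2 = d_n2 = a2_n2 = f_star_v = excess = f_nom = np.nan

        if ex1 is not None:
            slope29 = _accepted_slope(slopes, ex1.sample_id, "29N2")
            if slope29 is None:
                flags.append("ex1 29N2 rejected")
            else:
                p29 = volumetric_rate(slope29, ex1, config.porosity, atoms=False)
                a_n2 = anammox_ex1(p29, config.f_nh4_nominal)
        else:
            flags.append("no ex1 series")

        if ex2 is not None:
            f_nom = nominal_f_no3(config, ex2)
            slope29 = _accepted_slope(slopes, ex2.sample_id, "29N2")
            slope30 = _accepted_slope(slopes, ex2.sample_id, "30N2")
            if slope30 is None:
                flags.append("ex2 30N2 rejected: no denitrification rate")
            else:
                p30 = volumetric_rate(slope30, ex2, config.porosity, atoms=False)
                p29 = (volumetric_rate(slope29, ex2, config.porosity, atoms=False)
                       if slope29 is not None else None)
                if p29 is not None and np.isfinite(a_n2):
                    try:
                        f_star = infer_fstar(p29, p30, a_n2, f_nominal=f_nom)
                        f_star_v = f_star.value
                        d_n2 = denit_ex2(p30, f_star)
                        a2_n2 = anammox_ex2(p29, p30, f_star)
                        factor = 1e3 * slurry_water_volume_l(ex2, config.porosity) \
                            / ex2.volume_sediment_cm3
                        excess = excess_nitrate(
                            config.added_15no3, f_star,
                            LabelingFraction(f_nom, "NO3"), factor,
                        )
                    except InfeasibleInversionError as err:
                        flags.append(f"infeasible F* inversion: {err}")
                        d_n2 = denit_ex2(p30, f_nom)
                else:
                    # no matched anammox constraint: fall back to nominal F
                    flags.append("no A(Ex1) constraint: D from nominal F, no excess NO3-")
                    d_n2 = denit_ex2(p30, f_nom)
        else:
            flags.append("no ex2 series")

        rows.append({
            "station_id": station,
            "layer_top_cm": layer[0],
            "layer_bottom_cm": layer[1],
            "anammox_nmol_n_cm3_d": 2.0 * a_n2,
            "denit_nmol_n_cm3_d": 2.0 * d_n2,
            "anammox_ex2_nmol_n_cm3_d": 2.0 * a2_n2,
            "f_no3_nominal": f_nom,
            "f_no3_star": f_star_v,
            "excess_no3_nmol_cm3": excess,
            "flags": "; ".join(flags),
        })
    return pd.DataFrame(rows)


def areal_rate_table(layer_rates: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Depth-integrated areal fluxes and anammox fraction per station.

    Layers with absent (NA) rates contribute zero to the integral — the
    conservative choice matching integration only over depths with
    significant production.
    """
    rows = []
    for station, grp in layer_rates.groupby("station_id"):
        def integral(col: str) -> float:
            layers = [
                (r["layer_top_cm"], r["layer_bottom_cm"], r[col])
                for _, r in grp.iterrows() if np.isfinite(r[col])
            ]
            return depth_integrate(layers, config.integration_depth_cm) if layers else 0.0

        a_areal = integral("anammox_nmol_n_cm3_d")
        d_areal = integral("denit_nmol_n_cm3_d")
        ra = anammox_fraction(a_areal, d_areal) if (a_areal + d_areal) > 0 else np.nan
        rows.append({
            "station_id": station,
            "anammox_mmol_n_m2_d": a_areal,
            "denit_mmol_n_m2_d": d_areal,
            "total_mmol_n_m2_d": a_areal + d_areal,
            "ra": ra,
        })
    return pd.DataFrame(rows)


def core_table(
    series_list: list[IncubationSeries],
    slopes: pd.DataFrame,
    ra_by_station: dict[str, float],
    config: RunConfig,
) -> pd.DataFrame:
    """rIPT total N-loss per core station, partitioned with the station's
    slurry-derived anammox fraction."""
    rows = []
    for s in series_list:
        if s.experiment != "core":
            continue
        ra = ra_by_station.get(s.station_id)
        slope29 = _accepted_slope(slopes, s.sample_id, "29N2")
        slope30 = _accepted_slope(slopes, s.sample_id, "30N2")
        flags = []
        result = dict.fromkeys(
            ["ra", "R29_ratio", "nloss_total_mmol_n_m2_d",
             "denit_mmol_n_m2_d", "anammox_mmol_n_m2_d"], np.nan
        )
        if ra is None or not np.isfinite(ra):
            flags.append("no slurry ra for station")
        elif slope29 is None or slope30 is None:
            flags.append("rejected isotopologue channel")
        else:
            obs = PairingObservation(
                p29=areal_rate_core(slope29, config.porosity),
                p30=areal_rate_core(slope30, config.porosity),
                units_tag="umol_n2_m2_d",
            )
            try:
                core = ript_nloss(obs, ra)
                result = {
                    "ra": core.ra,
                    "R29_ratio": core.R29,
                    "nloss_total_mmol_n_m2_d": core.nloss_total,
                    "denit_mmol_n_m2_d": core.denit,
                    "anammox_mmol_n_m2_d": core.anammox,
                }
            except BenthicNLossError as err:
                flags.append(str(err))
        rows.append({
            "station_id": s.station_id, "sample_id": s.sample_id,
            **result, "flags": "; ".join(flags),
        })
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    incubation_series: list[IncubationSeries],
    nutrient_samples=None,
    qpcr_measurements=None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every stage and (optionally) write the report bundle as CSVs.

    Returns a dict of DataFrames: ``slopes``, ``slurry_rates``,
    ``areal_rates``, ``core_nloss``, and, when inputs are given,
    ``nstar``, ``gene_fractions`` and ``budget``.
    """
    slopes = slope_table(incubation_series, config)
    n_rej = int((~slopes["accepted"]).sum()) if len(slopes) else 0
    logger.info("slope filter: %d/%d channels accepted",
                len(slopes) - n_rej, len(slopes))
    layer_rates = slurry_rate_table(incubation_series, slopes, config)
    areal = areal_rate_table(layer_rates, config) if len(layer_rates) else pd.DataFrame(
        columns=["station_id", "anammox_mmol_n_m2_d", "denit_mmol_n_m2_d",
                 "total_mmol_n_m2_d", "ra"])
    ra_by_station = dict(zip(areal["station_id"], areal["ra"])) if len(areal) else {}
    cores = core_table(incubation_series, slopes, ra_by_station, config)
    out = {"slopes": slopes, "slurry_rates": layer_rates,
           "areal_rates": areal, "core_nloss": cores}

    if nutrient_samples:
        out["nstar"] = pd.DataFrame([
            {"station_id": ns.station_id, "depth_m": ns.depth_m,
             "nstar_umol_n_l": nstar(ns)}
            for ns in nutrient_samples
        ])

    if qpcr_measurements:
        by_key: dict[tuple, dict[str, object]] = {}
        for m in qpcr_measurements:
            by_key.setdefault((m.station_id, m.layer), {})[m.target] = m
        rows = []
        for (station, layer), pair in sorted(by_key.items()):
            amx, den = pair.get("anammox_nirS"), pair.get("denitrifier_nirS")
            row = {"station_id": station, "layer_top_cm": layer[0],
                   "layer_bottom_cm": layer[1],
                   "anammox_nirs_fraction": np.nan, "fraction_sd": np.nan,
                   "flags": ""}
            if amx is None or den is None:
                row["flags"] = "unpaired qPCR targets"
            else:
                try:
                    frac, sd = anammox_nirs_fraction(amx, den, with_sd=True)
                    row["anammox_nirs_fraction"], row["fraction_sd"] = frac, sd
                except BenthicNLossError as err:
                    row["flags"] = str(err)
            rows.append(row)
        out["gene_fractions"] = pd.DataFrame(rows)

    finite_totals = areal["total_mmol_n_m2_d"].dropna() if len(areal) else pd.Series(dtype=float)
    if len(finite_totals):
        mean_rate = float(finite_totals.mean())
        out["budget"] = pd.DataFrame([{
            "areal_rate_mmol_n_m2_d": mean_rate,
            "area_m2": config.area_omz_benthic_m2,
            "annual_loss_tg_n_yr": annual_basin_nloss(
                mean_rate, config.area_omz_benthic_m2,
                config.days_per_year, config.molar_mass_n,
            ),
        }])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(out_dir / f"{name}.csv", index=False, na_rep="NA")
        config.to_yaml(out_dir / "config_resolved.yaml")
    return out
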