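"""CSV readers and writers for the pipeline's tabular interfaces.

All files are plain CSV with a header row and the missing-value token
``NA``.  One incubation subsample per row; series are grouped by
``sample_id``.  Every writer emits units in the column names so no table
can be misread silently.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError
from .genes import QpcrMeasurement
from .isotope_signals import IncubationSeries
from .watercolumn import NutrientSample

NA = "NA"

INCUBATION_COLUMNS = [
    "sample_id", "experiment", "station_id", "layer_top_cm", "layer_bottom_cm",
    "time_h", "r29", "r30", "n28_umol_l", "volume_sediment_cm3", "volume_water_ml",
]


def read_incubation_csv(path: str | Path) -> list[IncubationSeries]:
    """Read incubation subsample rows and group them into series.

    Rows belonging to one series share a ``sample_id``; they are sorted by
    time.  Layer and volume columns may be NA for core incubations.
    """
    df = pd.read_csv(path, na_values=[NA])
    missing = set(INCUBATION_COLUMNS[:9]) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    series = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_h")
        exp = grp["experiment"].iloc[0]
        layer = None
        if not pd.isna(grp["layer_top_cm"].iloc[0]):
            layer = (float(grp["layer_top_cm"].iloc[0]), float(grp["layer_bottom_cm"].iloc[0]))
        v_sed = grp.get("volume_sediment_cm3")
        v_wat = grp.get("volume_water_ml")
        series.append(
            IncubationSeries(
                sample_id=str(sample_id),
                experiment=str(exp),
                station_id=str(grp["station_id"].iloc[0]),
                time_h=grp["time_h"].to_numpy(float),
                r29=grp["r29"].to_numpy(float),
                r30=grp["r30"].to_numpy(float),
                n28_conc=grp["n28_umol_l"].to_numpy(float),
                layer=layer,
                volume_sediment_cm3=None if v_sed is None or pd.isna(v_sed.iloc[0]) else float(v_sed.iloc[0]),
                volume_water_ml=None if v_wat is None or pd.isna(v_wat.iloc[0]) else float(v_wat.iloc[0]),
            )
        )
    return series


def write_incubation_csv(series: Iterable[IncubationSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for i, t in enumerate(s.time_h):
            rows.append({
                "sample_id": s.sample_id,
                "experiment": s.experiment,
                "station_id": s.station_id,
                "layer_top_cm": s.layer[0] if s.layer else np.nan,
                "layer_bottom_cm": s.layer[1] if s.layer else np.nan,
                "time_h": t,
                "r29": s.r29[i],
                "r30": s.r30[i],
                "n28_umol_l": np.asarray(s.n28_conc)[i],
                "volume_sediment_cm3": s.volume_sediment_cm3 if s.volume_sediment_cm3 else np.nan,
                "volume_water_ml": s.volume_water_ml if s.volume_water_ml else np.nan,
            })
    pd.DataFrame(rows, columns=INCUBATION_COLUMNS).to_csv(
        path, index=False, na_rep=NA
    )


def read_nutrient_csv(path: str | Path) -> list[NutrientSample]:
    """Read nutrient/oxygen profile rows (µmol l⁻¹; depth_m)."""
    df = pd.read_csv(path, na_values=[NA])
    required = {"depth_m", "nh4", "no2", "no3", "po4"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            NutrientSample(
                depth_m=float(row["depth_m"]),
                nh4=None if pd.isna(row["nh4"]) else float(row["nh4"]),
                no2=None if pd.isna(row["no2"]) else float(row["no2"]),
                no3=None if pd.isna(row["no3"]) else float(row["no3"]),
                po4=None if pd.isna(row["po4"]) else float(row["po4"]),
                o2=None if "o2" not in df.columns or pd.isna(row.get("o2")) else float(row["o2"]),
                station_id=str(row.get("station_id", "")),
            )
        )
    return out


def read_qpcr_csv(path: str | Path) -> list[QpcrMeasurement]:
    """Read a qPCR copy-number table.

    ``copies_per_mg`` of ``n.d.`` (or NA with ``below_detection`` truthy)
    parses to a below-detection measurement, which is excluded from
    fractions rather than treated as zero.
    """
    df = pd.read_csv(path, na_values=[NA], dtype={"copies_per_mg": str})
    required = {"station_id", "layer_top_cm", "layer_bottom_cm", "target", "copies_per_mg"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        raw = row["copies_per_mg"]
        nd = (isinstance(raw, str) and raw.strip().lower() in ("n.d.", "nd")) or pd.isna(raw)
        if not nd and "below_detection" in df.columns and bool(row["below_detection"]):
            nd = True
        out.append(
            QpcrMeasurement(
                station_id=str(row["station_id"]),
                layer=(float(row["layer_top_cm"]), float(row["layer_bottom_cm"])),
                target=str(row["target"]),
                copies_per_mg=None if nd else float(raw),
                sd=None if "sd" not in df.columns or pd.isna(row.get("sd")) else float(row["sd"]),
                below_detection=nd,
            )
        )
    return out
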