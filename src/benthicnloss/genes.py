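"""qPCR copy-number summaries: anammox share of the nirS pool and
cell-specific rates.

The nirS gene (cytochrome cd₁ nitrite reductase) occurs in phylogenetically
distinct variants in denitrifiers and in Scalindua-type anammox bacteria,
so target-specific qPCR assays partition the nitrite-reducing community.
Because nirS is a single-copy gene in sequenced anammox genomes, copy
numbers translate to cell numbers and volumetric rates to per-cell rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DivisionDomainError, InputError, UndefinedFractionError


@dataclass
class QpcrMeasurement:
    """One qPCR result: copies per mg dry sediment with its sd.

    A measurement below the detection limit is recorded with
    ``below_detection=True`` and ``copies_per_mg=None`` — never as zero,
    which would bias fractions.
    """

    station_id: str
    layer: tuple[float, float]
    target: str  # "denitrifier_nirS" | "anammox_nirS"
    copies_per_mg: float | None
    sd: float | None = None
    below_detection: bool = False

    def __post_init__(self):
        if self.target not in ("denitrifier_nirS", "anammox_nirS"):
            raise InputError(f"unknown qPCR target {self.target!r}")
        if self.below_detection:
            if self.copies_per_mg is not None:
                raise InputError(
                    "below-detection measurements must record copies as absent"
                )
        else:
            if self.copies_per_mg is None:
                raise InputError("detected measurements need a copy number")
            if not math.isfinite(self.copies_per_mg) or self.copies_per_mg < 0:
                raise InputError(f"copies must be >= 0, got {self.copies_per_mg}")
        if self.sd is not None and self.sd < 0:
            raise InputError("sd must be >= 0")


def anammox_nirs_fraction(
    anammox: QpcrMeasurement,
    denitrifier: QpcrMeasurement,
    with_sd: bool = False,
) -> float | tuple[float, float]:
    """Anammox share of total nirS copies, a/(a+d), in [0, 1].

    A target below detection contributes nothing to the numerator/denominator
    (it is excluded, not zeroed); if both targets are below detection the
    fraction is undefined.  With ``with_sd=True`` the first-order
    delta-method sd from the two measurement sds is returned alongside.
    """
    if (anammox.station_id, anammox.layer) != (denitrifier.station_id, denitrifier.layer):
        raise InputError("fraction requires measurements from the same station/layer")
    if anammox.target != "anammox_nirS" or denitrifier.target != "denitrifier_nirS":
        raise InputError("pass (anammox, denitrifier) measurements in that order")
    if anammox.below_detection and denitrifier.below_detection:
        raise UndefinedFractionError("both nirS targets below detection")
    a = 0.0 if anammox.below_detection else anammox.copies_per_mg
    d = 0.0 if denitrifier.below_detection else denitrifier.copies_per_mg
    if a + d == 0:
        raise UndefinedFractionError("total nirS copy number is zero")
    frac = a / (a + d)
    if not with_sd:
        return frac
    # delta method on f(a, d) = a/(a+d): df/da = d/(a+d)^2, df/dd = -a/(a+d)^2
    sa = anammox.sd or 0.0
    sd_ = denitrifier.sd or 0.0
    tot2 = (a + d) ** 2
    var = (d / tot2 * sa) ** 2 + (a / tot2 * sd_) ** 2
    return frac, math.sqrt(var)


def cell_specific_rate(
    volumetric_rate: float,
    copies_per_mg: float,
    bulk_density: float = 1.0,
    copies_per_cell: int = 1,
) -> float:
    """Per-cell rate in fmol N cell⁻¹ d⁻¹ from a volumetric rate and gene
    copy abundance.

    cells cm⁻³ = copies_per_mg · 10³ mg g⁻¹ · bulk_density / copies_per_cell;
    rate = volumetric_rate · 10⁶ (nmol → fmol) / cells cm⁻³.

    The dry bulk density (g dry sediment cm⁻³) is rarely reported with qPCR
    tables; the default of 1.0 is a placeholder and the result scales
    inversely with it — treat absolute per-cell rates accordingly.
    """
    if copies_per_mg <= 0:
        raise DivisionDomainError("copies_per_mg must be > 0")
    if bulk_density <= 0:
        raise InputError("bulk_density must be > 0")
    if copies_per_cell < 1:
        raise InputError("copies_per_cell must be >= 1")
    if volumetric_rate < 0:
        raise InputError("volumetric_rate must be >= 0")
    cells_per_cm3 = copies_per_mg * 1e3 * bulk_density / copies_per_cell
    return volumetric_rate * 1e6 / cells_per_cm3
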