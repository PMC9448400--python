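"""Drug loading / encapsulation efficiencies and calibration-line utilities.

For micelles prepared from a feed of ``polymer_mass_mg`` copolymer and
``drug_added_mg`` drug, with a measured drug content of
``drug_in_micelles_mg_per_g`` (mg drug per g of recovered micelle powder),

    DLE (%) = drug in micelles / (polymer + drug) x 100
    DEE (%) = drug in micelles / drug added        x 100

The micelle powder is composed of polymer + drug, so a content of c mg/g
is c/10 percent by mass, which is exactly the DLE.  Curcumin quantitation
runs through a spectrophotometric calibration line forced through the
origin (absorbance = slope x concentration).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "Formulation",
    "CalibrationLine",
    "compute_dle_dee",
    "fit_calibration",
    "absorbance_to_concentration",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding at report precision.

    Ties round away from zero on the shortest decimal representation of
    ``value`` (so 70.345 -> 70.35), matching how lab reports are printed;
    Python's banker's rounding would give 70.34.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


class UndefinedEfficiencyError(ZeroDivisionError):
    """DEE requested with no drug in the feed."""


class DegenerateDesignError(ValueError):
    """Calibration design cannot identify a slope (all-zero concentrations)."""


@dataclass(frozen=True)
class Formulation:
    """Micelle formulation: feed masses plus measured drug content.

    drug_in_micelles_mg_per_g is the assayed drug mass per gram of
    recovered (lyophilized) micelle powder; it cannot exceed 1000 mg/g.
    """

    polymer_mass_mg: float
    drug_added_mg: float
    drug_in_micelles_mg_per_g: float
    sample_id: str = ""

    def __post_init__(self):
        if self.polymer_mass_mg <= 0:
            raise ValueError("polymer_mass_mg must be > 0")
        if self.drug_added_mg < 0 or self.drug_in_micelles_mg_per_g < 0:
            raise ValueError("masses must be non-negative")
        if self.drug_in_micelles_mg_per_g > 1000:
            raise ValueError("drug content exceeds 1000 mg per g of micelles")


@dataclass(frozen=True)
class CalibrationLine:
    """Through-origin calibration: absorbance = slope x concentration (ug/ml)."""

    slope: float
    r_squared: float

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")


def compute_dle_dee(f: Formulation) -> tuple[float, float]:
    """Return (DLE %, DEE %), unrounded.

    DLE follows directly from the powder content: c mg drug per g of
    micelles (polymer+drug) is c/10 %.  DEE rescales DLE by the feed ratio:
    DEE = DLE x (polymer + drug) / drug_added.
    """
    dle = f.drug_in_micelles_mg_per_g / 10.0
    if f.drug_added_mg == 0:
        if f.drug_in_micelles_mg_per_g == 0:
            return 0.0, 0.0
        raise UndefinedEfficiencyError(
            "DEE undefined: drug found in micelles but none in the feed"
        )
    feed_fraction = f.drug_added_mg / (f.polymer_mass_mg + f.drug_added_mg)
    dee = dle / (100.0 * feed_fraction) * 100.0
    return dle, dee


def fit_calibration(concentrations, absorbances) -> CalibrationLine:
    """Least-squares through-origin calibration line.

    slope = sum(x*y)/sum(x^2); r^2 is computed against the through-origin
    model, r^2 = 1 - SS_res / SS_tot with SS_tot about the mean absorbance.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if x.size < 2 or x.shape != y.shape:
        raise ValueError("need >= 2 (concentration, absorbance) pairs")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise DegenerateDesignError("all concentrations are zero")
    slope = float(np.dot(x, y)) / sxx
    resid = y - slope * x
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return CalibrationLine(slope=slope, r_squared=float(np.clip(r2, 0.0, 1.0)))


def absorbance_to_concentration(absorbance: float, line: CalibrationLine) -> float:
    """Invert the calibration line: concentration (ug/ml) = A / slope."""
    if line.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return absorbance / line.slope
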