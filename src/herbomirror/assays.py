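"""Antioxidant assay calculators and composition/dose conversions.

DPPH: electron-transfer radical bleaching at 515 nm; scavenging is the
fractional loss of DPPH absorbance relative to the reagent blank, with a
sample blank correcting for the sample's own absorbance. Activity is
reported against a gallic acid standard curve (gallic-acid equivalents).

ORAC: hydrogen-atom-transfer protection of fluorescein from peroxyl
radicals; the readout is the area under the fluorescence decay curve,
net of the reagent blank, calibrated against Trolox (Trolox equivalents).

Dose conversions turn a constituent content (mg per g dry extract) at a
media dose (mg extract per mL) into a media concentration (ug/mL) and
onward to molarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from typing import NamedTuple

import numpy as np
from scipy.stats import linregress

__all__ = [
    "StandardCurve",
    "KineticTrace",
    "dpph_scavenging",
    "equivalents",
    "predict_response",
    "orac_net_auc",
    "dose_to_media_concentration",
    "mass_to_molar",
    "report_two_decimals",
]

MYO_INOSITOL_MW = 180.16  # g/mol
CHOLINE_MW = 104.17  # g/mol


@dataclass
class StandardCurve:
    """Linear calibration curve fitted by least squares."""

    concentrations: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    r2: float

    @classmethod
    def fit(cls, concentrations, responses) -> "StandardCurve":
        conc = np.asarray(concentrations, dtype=float)
        resp = np.asarray(responses, dtype=float)
        if conc.size != resp.size or conc.size < 3:
            raise ValueError("need >= 3 matched standard points")
        res = linregress(conc, resp)
        return cls(conc, resp, float(res.slope), float(res.intercept), float(res.rvalue**2))


@dataclass
class KineticTrace:
    """Fluorescence decay trace; times in seconds, strictly increasing."""

    times: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.size != self.fluorescence.size:
            raise ValueError("times and fluorescence must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def auc(self) -> float:
        return float(np.trapezoid(self.fluorescence, self.times))


class ScavengingResult(NamedTuple):
    percent: float
    out_of_range: bool


class EquivalentResult(NamedTuple):
    concentration: float
    extrapolated: bool


def dpph_scavenging(
    a_sample: float, a_reagent_blank: float, a_sample_blank: float = 0.0
) -> ScavengingResult:
    """Percent DPPH scavenging with sample-blank absorbance correction.

    % = 100 * (A_blank - (A_sample - A_sample_blank)) / A_blank, clipped
    to [0, 100]; values outside the range before clipping are flagged.
    """
    if a_reagent_blank <= 0:
        raise ValueError("reagent blank absorbance must be positive")
    raw = 100.0 * (a_reagent_blank - (a_sample - a_sample_blank)) / a_reagent_blank
    return ScavengingResult(float(np.clip(raw, 0.0, 100.0)), not 0.0 <= raw <= 100.0)


def predict_response(curve: StandardCurve, concentration: float) -> float:
    return curve.slope * concentration + curve.intercept


def equivalents(response: float, curve: StandardCurve) -> EquivalentResult:
    """Inverse-predict the standard concentration giving this response.

    Responses outside the span of the fitted standards are still inverted
    but flagged as extrapolated.
    """
    if curve.slope == 0:
        raise ValueError("standard curve has zero slope")
    conc = (response - curve.intercept) / curve.slope
    fitted = curve.slope * curve.concentrations + curve.intercept
    lo, hi = float(fitted.min()), float(fitted.max())
    return EquivalentResult(float(conc), not lo <= response <= hi)


def orac_net_auc(
    sample: KineticTrace, blank: KineticTrace, require_matched_grid: bool = False
) -> float:
    """Net area under the fluorescence decay curve: AUC(sample) - AUC(blank).

    Each trace is integrated by the trapezoid rule on its own time grid;
    set ``require_matched_grid`` for a strictly paired comparison, which
    fails if the grids differ.
    """
    if require_matched_grid and (
        sample.times.size != blank.times.size
        or not np.allclose(sample.times, blank.times)
    ):
        raise ValueError("paired net AUC requires identical time grids")
    return sample.auc() - blank.auc()


def dose_to_media_concentration(
    content_mg_per_g: float, dose_mg_per_ml: float = 2.5
) -> float:
    """Media concentration in ug/mL from content (mg/g) and dose (mg/mL).

    Dimensional identity: (mg constituent / g extract) x (mg extract / mL)
    = ug constituent / mL.
    """
    if content_mg_per_g < 0 or dose_mg_per_ml < 0:
        raise ValueError("content and dose must be nonnegative")
    return content_mg_per_g * dose_mg_per_ml


def mass_to_molar(conc_ug_per_ml: float, molar_mass_g_per_mol: float) -> float:
    """Micromolar concentration from ug/mL and molar mass (g/mol)."""
    if molar_mass_g_per_mol <= 0:
        raise ValueError("molar mass must be positive")
    return conc_ug_per_ml / molar_mass_g_per_mol * 1000.0


def report_two_decimals(value: float | str, mode: str = "truncate") -> float:
    """Two-decimal reporting helper (truncation by default).

    Composition tables in this domain conventionally truncate rather than
    round (549.575 -> 549.57). Pass the value as a string (or the exact
    operands via Decimal) to avoid binary-float artifacts; floats are
    first re-read through their shortest decimal repr.
    """
    d = Decimal(value) if isinstance(value, str) else Decimal(repr(value))
    rounding = {"truncate": ROUND_DOWN, "half_up": ROUND_HALF_UP}[mode]
    return float(d.quantize(Decimal("0.01"), rounding=rounding))


def dose_report(content_mg_per_g: str | float, dose_mg_per_ml: str | float = "2.5",
                mode: str = "truncate") -> float:
    """Exact-decimal dose conversion with two-decimal reporting."""
    c = Decimal(str(content_mg_per_g))
    d = Decimal(str(dose_mg_per_ml))
    if c < 0 or d < 0:
        raise ValueError("content and dose must be nonnegative")
    rounding = {"truncate": ROUND_DOWN, "half_up": ROUND_HALF_UP}[mode]
    return float((c * d).quantize(Decimal("0.01"), rounding=rounding))
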