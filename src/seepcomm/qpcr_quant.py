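"""Absolute qPCR quantification of 16S rRNA gene copies.

Standard curves are ordinary least squares of quantification cycle (Cq)
on log10(template copies); amplification efficiency follows from the
slope as 10^(-1/slope) - 1 (a slope of -3.3219 is perfect doubling).
Template mass converts to copies via the mean molecular weight of one
base pair, 660 g/mol.  Sample quantities are reported as copies per gram
of sediment and censored at the assay detection limit (per reaction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_data_io import ValidationError

__all__ = [
    "StandardCurve",
    "QuantResult",
    "mass_to_copies",
    "fit_standard_curve",
    "quantify",
    "PERFECT_DOUBLING_SLOPE",
]

AVOGADRO = 6.02214076e23
BP_MOLAR_MASS_G = 660.0
PERFECT_DOUBLING_SLOPE = -1.0 / np.log10(2.0)  # -3.3219...

#: Assay detection limits (copies per reaction) for the universal
#: bacterial and archaeal 16S primer sets used here.
DEFAULT_DETECTION_LIMITS_COPIES = {"bacteria": 27.0, "archaea": 178.0}


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution-series calibration: Cq = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValidationError(
                "standard-curve slope must be negative (Cq falls as template rises); "
                "check for inverted standards"
            )

    @property
    def efficiency(self) -> float:
        """Amplification efficiency fraction, 1.0 = perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def copies_from_cq(self, cq: float) -> float:
        return float(10.0 ** ((cq - self.intercept) / self.slope))

    def cq_from_copies(self, copies: float) -> float:
        return float(self.slope * np.log10(copies) + self.intercept)


@dataclass(frozen=True)
class QuantResult:
    """Absolute abundance for one sample, with detection-limit censoring."""

    copies_per_g: float
    copies_per_reaction: float
    censored: bool
    detection_limit_copies: float
    limit_basis: str = "per reaction"

    def __post_init__(self) -> None:
        if self.copies_per_g < 0:
            raise ValidationError("copies_per_g must be >= 0")


def mass_to_copies(dna_mass_ng: float, amplicon_bp: int) -> float:
    """Gene copies in a DNA mass, via 660 g/mol per base pair."""
    if dna_mass_ng <= 0 or amplicon_bp <= 0:
        raise ValidationError("dna_mass_ng and amplicon_bp must be > 0")
    grams = dna_mass_ng * 1e-9
    return grams / (amplicon_bp * BP_MOLAR_MASS_G) * AVOGADRO


def fit_standard_curve(standards: Sequence[tuple[float, float]]) -> StandardCurve:
    """OLS fit of Cq on log10(copies) over a dilution series.

    ``standards`` is a sequence of (copies, Cq) pairs covering at least three
    distinct dilution levels; replicate Cq values at a level are allowed and
    enter the regression individually.
    """
    if not standards:
        raise ValidationError("no standards provided")
    copies = np.array([c for c, _ in standards], dtype=float)
    cq = np.array([q for _, q in standards], dtype=float)
    if np.any(copies <= 0):
        raise ValidationError("standard copies must be > 0")
    if np.unique(copies).size < 3:
        raise ValidationError("need >= 3 distinct dilution levels for a standard curve")
    res = stats.linregress(np.log10(copies), cq)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2))


def quantify(cq: float | Sequence[float], curve: StandardCurve,
             elution_volume_uL: float, template_uL: float, sediment_g: float,
             detection_limit_copies: float = 0.0) -> QuantResult:
    """Convert observed Cq to 16S gene copies per gram of sediment.

    ``cq`` may be a single value or technical replicates (averaged
    arithmetically before conversion).  Copies per reaction scale to copies
    per gram by the eluate-to-template volume ratio over the extracted
    sediment mass.  Results below ``detection_limit_copies`` (per reaction)
    are flagged censored but still report the point estimate.
    """
    if sediment_g <= 0 or template_uL <= 0 or elution_volume_uL <= 0:
        raise ValidationError("extraction volumes and sediment mass must be > 0")
    mean_cq = float(np.mean(np.asarray(cq, dtype=float)))
    per_rxn = curve.copies_from_cq(mean_cq)
    per_g = per_rxn * (elution_volume_uL / template_uL) / sediment_g
    return QuantResult(
        copies_per_g=per_g, copies_per_reaction=per_rxn,
        censored=per_rxn < detection_limit_copies,
        detection_limit_copies=detection_limit_copies,
    )
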