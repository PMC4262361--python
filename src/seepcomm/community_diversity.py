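"""Clone-library diversity statistics and sulfate-reducer tallies.

Ribotype abundance vectors are summarised with the Shannon–Wiener index
(natural log), the Chao1 richness estimator and Good's coverage; printed
percentage compositions are reconstructed to exact integer counts by
largest-remainder apportionment.  A genus-level registry flags potential
sulfate reducers so that the flagged fraction of each library can be
tallied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np

from .core_data_io import CloneLibrary, SulfateReducerRegistry, ValidationError

__all__ = [
    "DiversitySummary",
    "counts_from_percentages",
    "shannon",
    "chao1",
    "goods_coverage",
    "summarize_library",
    "sr_fraction",
    "default_sr_registry",
]


@dataclass(frozen=True)
class DiversitySummary:
    """Alpha-diversity summary of one clone library."""

    s_obs: int
    shannon_nats: float
    chao1: float
    chao1_bias_corrected: float
    coverage_pct: float
    f1: int
    f2: int

    def __post_init__(self) -> None:
        ceiling = np.log(self.s_obs) if self.s_obs > 1 else 0.0
        if not (-1e-9 <= self.shannon_nats <= ceiling + 1e-9):
            raise ValidationError(
                f"Shannon index {self.shannon_nats:.4f} outside [0, ln(S_obs)] "
                f"= [0, {ceiling:.4f}] for S_obs={self.s_obs}"
            )
        if self.chao1 < self.s_obs - 1e-9:
            raise ValidationError("Chao1 must be >= observed richness")
        if not (0.0 <= self.coverage_pct <= 100.0):
            raise ValidationError("coverage must lie in [0, 100]%")


def counts_from_percentages(percents: Sequence[float], n_clones: int,
                            tolerance: float = 1.0) -> list[int]:
    """Apportion ``n_clones`` into integer counts matching printed percentages.

    Largest-remainder (Hamilton) apportionment: each ribotype gets the floor
    of its exact quota ``percent/100 * n_clones``, and the leftover clones go
    one each to the largest fractional remainders.  Ties are broken by input
    order, and the counts always sum to ``n_clones`` exactly.
    """
    if n_clones <= 0:
        raise ValidationError("n_clones must be positive")
    percents = [float(p) for p in percents]
    total = sum(percents)
    if abs(total - 100.0) > tolerance:
        raise ValidationError(f"percentages sum to {total:g}, not 100 ± {tolerance:g}")
    quotas = [p / 100.0 * n_clones for p in percents]
    counts = [int(np.floor(q)) for q in quotas]
    leftover = n_clones - sum(counts)
    # stable sort -> earlier entries win remainder ties
    by_remainder = sorted(range(len(quotas)), key=lambda i: -(quotas[i] - counts[i]))
    for i in by_remainder[:leftover]:
        counts[i] += 1
    return counts


def _as_counts(counts: Sequence[int]) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValidationError("abundance vector is empty")
    if np.any(c < 1):
        raise ValidationError("all abundances must be >= 1")
    return c


def shannon(counts: Sequence[int]) -> float:
    """Shannon–Wiener index H = -sum p_i ln p_i in nats."""
    c = _as_counts(counts)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def chao1(counts: Sequence[int], variant: str = "classic") -> float:
    """Chao1 richness estimate from singleton (F1) and doubleton (F2) counts.

    classic:         S_obs + F1^2 / (2 F2), falling back to
                     S_obs + F1 (F1 - 1) / 2 when F2 = 0
    bias_corrected:  S_obs + F1 (F1 - 1) / (2 (F2 + 1))
    """
    c = _as_counts(counts)
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if variant == "classic":
        if f2 > 0:
            return s_obs + f1 ** 2 / (2.0 * f2)
        return s_obs + f1 * (f1 - 1) / 2.0
    if variant == "bias_corrected":
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    raise ValidationError(f"unknown Chao1 variant {variant!r}")


def goods_coverage(counts: Sequence[int]) -> float:
    """Good's coverage C = (1 - F1/N) * 100, in percent."""
    c = _as_counts(counts)
    f1 = int((c == 1).sum())
    return float((1.0 - f1 / c.sum()) * 100.0)


def summarize_library(lib: CloneLibrary) -> DiversitySummary:
    """Bundle observed richness, Shannon, both Chao1 variants and coverage."""
    counts = lib.counts
    return DiversitySummary(
        s_obs=counts.size,
        shannon_nats=shannon(counts),
        chao1=chao1(counts, "classic"),
        chao1_bias_corrected=chao1(counts, "bias_corrected"),
        coverage_pct=goods_coverage(counts),
        f1=int((counts == 1).sum()),
        f2=int((counts == 2).sum()),
    )


def sr_fraction(lib: CloneLibrary,
                registry: SulfateReducerRegistry) -> tuple[float, dict[str, float]]:
    """Fraction of clones belonging to flagged potential-sulfate-reducer genera.

    Ribotypes without a genus annotation count as non-reducers; genera absent
    from the registry warn and count as non-reducers.  Returns the overall
    fraction and the per-genus clone-fraction breakdown of flagged genera.
    """
    flagged = 0
    breakdown: dict[str, float] = {}
    for r in lib.ribotypes:
        if r.genus is None:
            continue
        if r.genus not in registry.entries:
            warnings.warn(f"genus {r.genus!r} not in registry; counted as non-reducer",
                          stacklevel=2)
            continue
        if registry.is_reducer(r.genus):
            flagged += r.count
            breakdown[r.genus] = breakdown.get(r.genus, 0.0) + r.count / lib.n_clones
    return flagged / lib.n_clones, breakdown


def default_sr_registry() -> SulfateReducerRegistry:
    """Registry of the genera treated as potential sulfate reducers here.

    Flags genera whose cultured members respire sulfate (or sulfite), with
    literature-typical optimum growth-temperature ranges (°C) as orientation;
    the ranges are informational and do not enter the fraction tally.  The
    registry is mutable: extend it with ``registry.add(...)``.
    """
    entries: dict[str, tuple[bool, tuple[float, float] | None]] = {
        # mesophilic sulfate/sulfite reducers
        "Desulfovibrio": (True, (25.0, 40.0)),
        "Desulfonatronum": (True, (35.0, 40.0)),
        "Desulforhabdus": (True, (30.0, 37.0)),
        "Desulfotomaculum": (True, (30.0, 65.0)),
        "Desulfitibacter": (True, (25.0, 40.0)),
        # thermophiles
        "Thermodesulfovibrio": (True, (55.0, 65.0)),
        "Thermacetogenium": (True, (55.0, 65.0)),
        "Thermodesulfobacterium": (True, (65.0, 75.0)),
        # archaea
        "Archaeoglobus": (True, (70.0, 83.0)),
        "Thermococcus": (True, (75.0, 88.0)),  # S0/thiosulfate reducer, flagged per classification scheme
        # common non-reducing genera seen in these libraries
        "Thermotoga": (False, None),
        "Dictyoglomus": (False, None),
        "Propionibacterium": (False, None),
        "Thermoanaerobacter": (False, None),
        "Thermosyntropha": (False, None),
        "Methanosaeta": (False, None),
        "Thermovirga": (False, None),
        "Desulfuromonas": (False, None),  # metal reducer, not a sulfate reducer
    }
    return SulfateReducerRegistry(entries=entries)
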