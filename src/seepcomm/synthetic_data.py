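"""Seeded generators emulating the incubation study's data-generating structure.

Three generators cover the pipeline's inputs:

* sulfate-depletion time series per temperature — falling logistic with
  temperature-dependent rate and lag (active at 40-80 °C, flat at 90 °C)
  plus Gaussian measurement noise;
* clone libraries — multinomial draws from temperature-dependent community
  profiles transcribed from the dominant printed ribotype percentages
  (minor-ribotype tails are synthetic fill, as the originals are unprinted);
* fluid samples — the two-end-member mixing forward model plus tracer noise.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data_io import CloneLibrary, FluidSample, IncubationSeries, Ribotype, ValidationError
from .endmember_mixing import MixingModel, default_ktl_model, forward_mix

__all__ = [
    "LogisticParams",
    "SyntheticConfig",
    "gen_incubation",
    "gen_library",
    "gen_libraries",
    "gen_fluids",
    "default_logistic_params",
    "default_community_profiles",
    "DEFAULT_LIBRARY_SIZES",
    "DEFAULT_TIME_GRID_H",
]

#: Sampling schedule: days 0, 2, 5, 10, 15, 20, 25, 30 in hours.
DEFAULT_TIME_GRID_H = tuple(24.0 * d for d in (0, 2, 5, 10, 15, 20, 25, 30))

#: Clones per library, (domain, treatment) -> n.
DEFAULT_LIBRARY_SIZES: dict[tuple[str, str], int] = {
    ("bacteria", "40C"): 42, ("bacteria", "50C"): 56, ("bacteria", "60C"): 59,
    ("bacteria", "70C"): 56, ("bacteria", "80C"): 36,
    ("archaea", "40C"): 56, ("archaea", "50C"): 58, ("archaea", "60C"): 25,
    ("archaea", "70C"): 41, ("archaea", "80C"): 35,
}


@dataclass(frozen=True)
class LogisticParams:
    """Generating parameters of one temperature's depletion curve."""

    S0_uM: float
    S_inf_uM: float
    k_per_h: float
    t0_h: float
    active: bool

    def __post_init__(self) -> None:
        if not self.active and self.k_per_h != 0.0:
            raise ValidationError("inactive temperatures must have k = 0")

    @property
    def r_max_uM_per_h(self) -> float:
        return (self.S0_uM - self.S_inf_uM) * self.k_per_h / 4.0


def default_logistic_params() -> dict[float, LogisticParams]:
    """Per-temperature depletion parameters matching the study regime.

    Starting sulfate lies in the supplied 1.3-2.0 mM range; k is set so the
    analytic maximum rate (S0 - S_inf) k / 4 equals the reported per-
    temperature maxima (7.3, 5.4, 3.3, 9.7 and 13.9 µM/h at 40-80 °C);
    70-80 °C get a pronounced lag (large t0, the sigmoidal regime) while
    40-60 °C consume from the first sampling; 90 °C is inactive.
    """
    def k_for(r_max: float, S0: float) -> float:
        return 4.0 * r_max / S0

    return {
        40.0: LogisticParams(1500.0, 0.0, k_for(7.3, 1500.0), 80.0, True),
        50.0: LogisticParams(1500.0, 0.0, k_for(5.4, 1500.0), 100.0, True),
        60.0: LogisticParams(1500.0, 0.0, k_for(3.3, 1500.0), 120.0, True),
        70.0: LogisticParams(2000.0, 0.0, k_for(9.7, 2000.0), 360.0, True),
        80.0: LogisticParams(2000.0, 0.0, k_for(13.9, 2000.0), 360.0, True),
        90.0: LogisticParams(1500.0, 1500.0, 0.0, 0.0, False),
    }


def default_community_profiles() -> dict[tuple[str, str], list[tuple[str, str | None, float]]]:
    """Temperature-dependent community profiles as (label, genus, probability).

    Dominant ribotype probabilities are the printed library percentages
    (e.g. 80 °C bacteria 53/22/25% Thermotoga/Dictyoglomus/Propionibacterium;
    50 °C bacteria led by Thermodesulfovibrio at 54%); the minor-ribotype
    tails, whose true abundances are unprinted, are spread evenly and their
    labels carry a ``syn`` prefix to mark them as synthetic fill.
    """
    def tail(total: float, k: int, start: int = 1) -> list[tuple[str, None, float]]:
        return [(f"syn_minor_{i}", None, total / k) for i in range(start, start + k)]

    return {
        ("bacteria", "40C"): [
            ("Desulfovibrio_R1", "Desulfovibrio", 0.17),
            ("Desulfonatronum_R1", "Desulfonatronum", 0.12),
            ("Desulforhabdus_R1", "Desulforhabdus", 0.09),
            ("Desulfuromonas_R1", "Desulfuromonas", 0.05),
            ("Desulfitibacter_R1", "Desulfitibacter", 0.12),
            ("Desulfotomaculum_R1", "Desulfotomaculum", 0.09),
            *tail(0.36, 8),
        ],
        ("bacteria", "50C"): [
            ("Thermodesulfovibrio_R1", "Thermodesulfovibrio", 0.54),
            ("Desulfovibrio_R2", "Desulfovibrio", 0.25),
            *tail(0.21, 8),
        ],
        ("bacteria", "60C"): [
            ("Thermodesulfovibrio_R1", "Thermodesulfovibrio", 0.39),
            ("Thermacetogenium_R1", "Thermacetogenium", 0.25),
            ("Thermosyntropha_R1", "Thermosyntropha", 0.16),
            *tail(0.20, 9),
        ],
        ("bacteria", "70C"): [
            ("Thermacetogenium_R1", "Thermacetogenium", 0.68),
            ("Thermoanaerobacter_R1", "Thermoanaerobacter", 0.13),
            *tail(0.19, 5),
        ],
        ("bacteria", "80C"): [
            ("Thermotoga_R1", "Thermotoga", 0.53),
            ("Dictyoglomus_R1", "Dictyoglomus", 0.22),
            ("Propionibacterium_R1", "Propionibacterium", 0.25),
        ],
        ("archaea", "40C"): [
            ("Methanosaeta_R1", "Methanosaeta", 0.95),
            ("Archaeoglobus_R1", "Archaeoglobus", 0.05),
        ],
        ("archaea", "50C"): [
            ("Methanosaeta_R1", "Methanosaeta", 0.90),
            ("Thermococcus_R1", "Thermococcus", 0.04),
            ("Archaeoglobus_R1", "Archaeoglobus", 0.03),
            *tail(0.03, 2),
        ],
        ("archaea", "60C"): [
            ("Archaeoglobus_R1", "Archaeoglobus", 0.60),
            ("MCG_R1", None, 0.40),
        ],
        ("archaea", "70C"): [("Archaeoglobus_R1", "Archaeoglobus", 1.0)],
        ("archaea", "80C"): [("Archaeoglobus_R1", "Archaeoglobus", 1.0)],
    }


@dataclass
class SyntheticConfig:
    """Bundle of generator settings; defaults emulate the study conditions."""

    seed: int = 0
    temperatures_C: tuple[float, ...] = (40.0, 50.0, 60.0, 70.0, 80.0, 90.0)
    logistic_params: dict[float, LogisticParams] = field(default_factory=default_logistic_params)
    time_grid_h: tuple[float, ...] = DEFAULT_TIME_GRID_H
    noise_sd_uM: float = 30.0  # ~2% of 1.5 mM, the stated analytical uncertainty
    community_profiles: dict[tuple[str, str], list[tuple[str, str | None, float]]] = field(
        default_factory=default_community_profiles)
    library_sizes: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_LIBRARY_SIZES))
    mixing_f_range: tuple[float, float] = (0.05, 0.19)
    tracer_noise_frac: float = 0.02

    def __post_init__(self) -> None:
        for key, profile in self.community_profiles.items():
            total = sum(p for _, _, p in profile)
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"profile {key}: probabilities sum to {total}, not 1")


def gen_incubation(config: SyntheticConfig) -> list[IncubationSeries]:
    """Noisy per-temperature sulfate depletion series on the configured grid."""
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.time_grid_h, dtype=float)
    out: list[IncubationSeries] = []
    for temp in config.temperatures_C:
        p = config.logistic_params[temp]
        if p.active:
            s = p.S_inf_uM + (p.S0_uM - p.S_inf_uM) / (1.0 + np.exp(p.k_per_h * (t - p.t0_h)))
        else:
            s = np.full_like(t, p.S0_uM)
        s = s + rng.normal(0.0, config.noise_sd_uM, size=t.shape)
        out.append(IncubationSeries(
            temperature_C=temp, times_h=t, sulfate_uM=np.clip(s, 0.0, None),
            label=f"synthetic_{temp:g}C",
        ))
    return out


def gen_library(profile: list[tuple[str, str | None, float]], n_clones: int,
                seed: int | np.random.Generator, domain: str = "bacteria",
                treatment: str = "synthetic") -> CloneLibrary:
    """Multinomial clone library drawn from a (label, genus, probability) profile.

    Ribotypes drawing zero clones are dropped, mirroring what a real library
    can observe.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = np.array([p for _, _, p in profile], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError("profile probabilities must sum to 1")
    counts = rng.multinomial(n_clones, probs)
    ribotypes = tuple(
        Ribotype(label, int(c), genus)
        for (label, genus, _), c in zip(profile, counts) if c > 0
    )
    return CloneLibrary(domain=domain, treatment=treatment,
                        n_clones=n_clones, ribotypes=ribotypes)


def gen_libraries(config: SyntheticConfig) -> list[CloneLibrary]:
    """One library per configured (domain, treatment) profile."""
    rng = np.random.default_rng(config.seed)
    libs = []
    for (domain, treatment), profile in config.community_profiles.items():
        n = config.library_sizes.get((domain, treatment), 50)
        libs.append(gen_library(profile, n, rng, domain=domain, treatment=treatment))
    return libs


def gen_fluids(model: MixingModel | None = None,
               f_values: "np.ndarray | list[float] | None" = None,
               n_samples: int = 4,
               f_range: tuple[float, float] = (0.05, 0.19),
               tracer_noise_frac: float = 0.02,
               seed: int = 0) -> tuple[list[FluidSample], np.ndarray]:
    """Fluid samples from the mixing forward model with tracer noise.

    Cl and Sr get multiplicative log-normal noise of scale
    ``tracer_noise_frac``; the isotope ratio gets additive noise scaled by
    the end-member ratio span.  Returns the samples and the true saline
    fractions so inversion accuracy can be scored.
    """
    model = model or default_ktl_model()
    rng = np.random.default_rng(seed)
    if f_values is None:
        f_values = rng.uniform(*f_range, size=n_samples)
    fs = np.asarray(f_values, dtype=float)
    span = abs(model.saline.ratio_87_86 - model.fresh.ratio_87_86)
    samples: list[FluidSample] = []
    for i, f in enumerate(fs):
        Cl, Sr, ratio = forward_mix(float(f), model)
        if tracer_noise_frac > 0:
            Cl *= np.exp(rng.normal(0.0, tracer_noise_frac))
            Sr *= np.exp(rng.normal(0.0, tracer_noise_frac))
            ratio += rng.normal(0.0, tracer_noise_frac * span)
        samples.append(FluidSample(site=f"synthetic_{i}", Cl_mM=Cl, Sr_uM=Sr,
                                   ratio_87_86=ratio))
    return samples, fs
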