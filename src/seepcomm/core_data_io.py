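"""Domain types, table schemas and readers shared by all analysis stages.

The package works from long-format CSV/TSV tables with a header row in which
each column may declare its unit as ``name:unit`` (e.g. ``sulfate:uM``,
``time:d``).  Time columns declared in days are converted to hours at parse
time; hours are the internal time unit throughout.  The literal token ``BDL``
is recognised as a below-detection-limit (censored) measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IncubationSeries",
    "Ribotype",
    "CloneLibrary",
    "SulfateReducerRegistry",
    "FluidSample",
    "EndMember",
    "BudgetInputs",
    "CensoredValue",
    "SchemaError",
    "ValidationError",
    "handle_bdl",
    "read_incubation_table",
    "write_incubation_table",
    "read_clone_library_table",
    "write_clone_library_table",
    "read_fluid_table",
    "write_fluid_table",
    "load_ktl_fluid_fixture",
]

BDL_TOKEN = "BDL"
NA_TOKENS = ("NA", "")


class SchemaError(ValueError):
    """A required column is missing or a declared unit is unsupported."""


class ValidationError(ValueError):
    """Table contents violate a domain invariant (monotonicity, sums, signs)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IncubationSeries:
    """Sulfate-versus-time record for one incubation temperature.

    Parameters
    ----------
    temperature_C : float
        Incubation temperature in degrees Celsius.
    times_h : array-like of float
        Sampling times in hours since inoculation; strictly increasing.
    sulfate_uM : array-like of float
        Sulfate concentration (µM) at each sampling time; non-negative.
    label : str
        Free-text site/replicate label.
    """

    temperature_C: float
    times_h: np.ndarray
    sulfate_uM: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        s = np.asarray(self.sulfate_uM, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "sulfate_uM", s)
        if t.ndim != 1 or s.shape != t.shape:
            raise ValidationError("times_h and sulfate_uM must be 1-D and equal length")
        if t.size and np.any(np.diff(t) <= 0):
            bad = np.nonzero(np.diff(t) <= 0)[0] + 1
            raise ValidationError(
                f"times_h must be strictly increasing; offending rows {bad.tolist()}"
            )
        if np.any(s < 0):
            raise ValidationError("sulfate_uM values must be >= 0")

    def __len__(self) -> int:
        return self.times_h.size


@dataclass(frozen=True)
class Ribotype:
    """One operational taxonomic unit of a clone library (a unique RFLP type)."""

    label: str
    count: int
    genus: str | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValidationError(f"ribotype {self.label!r}: count must be >= 1")


@dataclass(frozen=True)
class CloneLibrary:
    """Ribotype abundances for one domain and incubation treatment.

    ``sum(counts) == n_clones`` is enforced; ribotype labels must be unique.
    """

    domain: str
    treatment: str
    n_clones: int
    ribotypes: tuple[Ribotype, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ribotypes", tuple(self.ribotypes))
        if self.domain not in ("bacteria", "archaea"):
            raise ValidationError(f"domain must be 'bacteria' or 'archaea', got {self.domain!r}")
        labels = [r.label for r in self.ribotypes]
        if len(set(labels)) != len(labels):
            raise ValidationError("ribotype labels must be unique within a library")
        total = sum(r.count for r in self.ribotypes)
        if total != self.n_clones:
            raise ValidationError(
                f"library {self.domain}/{self.treatment}: counts sum to {total}, "
                f"declared n_clones={self.n_clones} (discrepancy {self.n_clones - total:+d})"
            )

    @property
    def counts(self) -> np.ndarray:
        return np.array([r.count for r in self.ribotypes], dtype=int)


@dataclass
class SulfateReducerRegistry:
    """Genus-level lookup of potential sulfate reducers.

    ``entries`` maps genus name to ``(is_potential_sulfate_reducer,
    optimum_temperature_range_C or None)``.
    """

    entries: dict[str, tuple[bool, tuple[float, float] | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for genus, (_, rng) in self.entries.items():
            if rng is not None and rng[0] > rng[1]:
                raise ValidationError(f"{genus}: temperature range low must be <= high")

    def is_reducer(self, genus: str | None) -> bool:
        if genus is None:
            return False
        return self.entries.get(genus, (False, None))[0]

    def add(self, genus: str, is_reducer: bool,
            optimum_range_C: tuple[float, float] | None = None) -> None:
        if optimum_range_C is not None and optimum_range_C[0] > optimum_range_C[1]:
            raise ValidationError(f"{genus}: temperature range low must be <= high")
        self.entries[genus] = (is_reducer, optimum_range_C)


@dataclass(frozen=True)
class FluidSample:
    """Conservative-tracer and isotope composition of one sampled fluid."""

    site: str
    Cl_mM: float | None = None
    Sr_uM: float | None = None
    ratio_87_86: float | None = None
    analytes: Mapping[str, "CensoredValue"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.Cl_mM is not None and self.Cl_mM <= 0:
            raise ValidationError(f"{self.site}: Cl_mM must be > 0 when present")
        if self.ratio_87_86 is not None and not (0.70 < self.ratio_87_86 < 0.73):
            warnings.warn(
                f"{self.site}: 87Sr/86Sr = {self.ratio_87_86} outside the "
                "(0.70, 0.73) range typical of this system", stacklevel=2,
            )


@dataclass(frozen=True)
class EndMember:
    """A mixing end member: chloride, strontium and Sr-isotope composition."""

    label: str
    Cl_mM: float
    Sr_uM: float
    ratio_87_86: float

    def __post_init__(self) -> None:
        for name in ("Cl_mM", "Sr_uM", "ratio_87_86"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"end member {self.label!r}: {name} must be finite and positive")


@dataclass(frozen=True)
class BudgetInputs:
    """Inputs to the stoichiometric electron-donor budget."""

    doc_mM: float
    dilution_factor: float
    supplied_sulfate_mM: tuple[float, float]
    carbon_per_sulfate: float = 2.0

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise ValidationError("dilution_factor must be >= 1")
        lo, hi = self.supplied_sulfate_mM
        if lo > hi:
            raise ValidationError("supplied_sulfate_mM range must satisfy low <= high")
        if self.carbon_per_sulfate <= 0:
            raise ValidationError("carbon_per_sulfate must be > 0")


# ---------------------------------------------------------------------------
# Below-detection-limit handling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CensoredValue:
    """A measurement that may be censored at a detection limit.

    ``value`` is the number used in downstream arithmetic; for censored
    entries it is derived from the detection limit by ``policy``
    (``zero`` | ``half-limit`` | ``limit``), and the policy is retained so
    output metadata can record how the censoring was resolved.
    """

    value: float
    unit: str = ""
    below_detection: bool = False
    detection_limit: float | None = None
    policy: str | None = None


_BDL_POLICIES = {"zero": 0.0, "half-limit": 0.5, "limit": 1.0}


def handle_bdl(value: float | str | None, detection_limit: float,
               policy: str = "half-limit", unit: str = "") -> CensoredValue:
    """Resolve a possibly below-detection measurement to a usable number.

    ``value`` may be a number, or the literal ``"BDL"`` / ``None`` for a
    censored result.  ``detection_limit`` must be positive and in the same
    unit as the measurement.
    """
    if detection_limit <= 0:
        raise ValidationError("detection_limit must be > 0")
    if policy not in _BDL_POLICIES:
        raise ValidationError(f"unknown BDL policy {policy!r}; use one of {sorted(_BDL_POLICIES)}")
    censored = value is None or (isinstance(value, str) and value.strip().upper() == BDL_TOKEN)
    if censored:
        return CensoredValue(
            value=_BDL_POLICIES[policy] * detection_limit, unit=unit,
            below_detection=True, detection_limit=detection_limit, policy=policy,
        )
    v = float(value)
    if v < 0:
        raise ValidationError(f"measured value {v} must be >= 0")
    return CensoredValue(value=v, unit=unit, below_detection=False,
                         detection_limit=detection_limit, policy=policy)


# ---------------------------------------------------------------------------
# Header / unit handling
# ---------------------------------------------------------------------------

def _split_header(col: str) -> tuple[str, str | None]:
    """Split ``name:unit`` headers; a bare name has no declared unit."""
    if ":" in col:
        name, unit = col.split(":", 1)
        return name.strip(), unit.strip()
    return col.strip(), None


_TIME_FACTORS_TO_H = {None: 1.0, "h": 1.0, "hr": 1.0, "hours": 1.0, "d": 24.0, "day": 24.0, "days": 24.0}
_SULFATE_FACTORS_TO_UM = {None: 1.0, "uM": 1.0, "mM": 1000.0}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _require(columns: Mapping[str, str], *names: str) -> None:
    missing = [n for n in names if n not in columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


# ---------------------------------------------------------------------------
# Incubation tables
# ---------------------------------------------------------------------------

def read_incubation_table(path: str | Path,
                          schema: Mapping[str, str] | None = None) -> list[IncubationSeries]:
    """Read a long-format incubation table into per-temperature series.

    Required columns: ``temperature``, ``time`` and ``sulfate`` (an optional
    ``schema`` maps these canonical names to the file's column names).  Rows
    are grouped by temperature and sorted by time; declared units (``time:d``,
    ``sulfate:mM``) are converted to hours and µM.
    """
    df = _read_table(path)
    name_map: dict[str, str] = {}   # canonical -> actual column label
    units: dict[str, str | None] = {}
    for col in df.columns:
        name, unit = _split_header(col)
        canonical = name
        if schema:
            for want, have in schema.items():
                if name == have:
                    canonical = want
        name_map[canonical] = col
        units[canonical] = unit
    _require(name_map, "temperature", "time", "sulfate")

    t_unit, s_unit = units.get("time"), units.get("sulfate")
    if t_unit not in _TIME_FACTORS_TO_H:
        raise SchemaError(f"unsupported time unit {t_unit!r}")
    if s_unit not in _SULFATE_FACTORS_TO_UM:
        raise SchemaError(f"unsupported sulfate unit {s_unit!r}")

    out = pd.DataFrame({
        "temperature": pd.to_numeric(df[name_map["temperature"]]),
        "time_h": pd.to_numeric(df[name_map["time"]]) * _TIME_FACTORS_TO_H[t_unit],
        "sulfate_uM": pd.to_numeric(df[name_map["sulfate"]]) * _SULFATE_FACTORS_TO_UM[s_unit],
    })
    out["label"] = df[name_map["label"]] if "label" in name_map else ""

    series: list[IncubationSeries] = []
    for (temp, label), grp in out.groupby(["temperature", "label"], sort=True):
        grp = grp.sort_values("time_h")
        dup = grp["time_h"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate times at {temp} °C: rows {grp.index[dup].tolist()}"
            )
        series.append(IncubationSeries(
            temperature_C=float(temp),
            times_h=grp["time_h"].to_numpy(),
            sulfate_uM=grp["sulfate_uM"].to_numpy(),
            label=str(label),
        ))
    return series


def write_incubation_table(series: Iterable[IncubationSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for t, v in zip(s.times_h, s.sulfate_uM):
            rows.append({"temperature:C": s.temperature_C, "time:h": t,
                         "sulfate:uM": v, "label": s.label})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Clone-library tables
# ---------------------------------------------------------------------------

def read_clone_library_table(path: str | Path) -> list[CloneLibrary]:
    """Read a long-format ribotype table (one row per ribotype).

    Required columns: ``domain``, ``treatment``, ``ribotype`` and either
    ``count`` or ``percent`` + ``n_clones``.  Percent rows are converted to
    exact integer counts by largest-remainder apportionment.
    """
    from . import community_diversity  # local import: avoids a cycle

    df = _read_table(path)
    cols = {_split_header(c)[0]: c for c in df.columns}
    _require(cols, "domain", "treatment", "ribotype")
    if "count" not in cols and not ("percent" in cols and "n_clones" in cols):
        raise SchemaError("missing required column(s): count (or percent + n_clones)")

    libraries: list[CloneLibrary] = []
    for (domain, treatment), grp in df.groupby([cols["domain"], cols["treatment"]], sort=False):
        genus_col = cols.get("genus")
        genera = [
            (None if g is None or str(g).strip() in ("", "none", "NA") else str(g).strip())
            for g in (grp[genus_col] if genus_col else [None] * len(grp))
        ]
        labels = grp[cols["ribotype"]].astype(str).tolist()
        if "count" in cols and grp[cols["count"]].str.strip().ne("").all():
            counts = pd.to_numeric(grp[cols["count"]]).astype(int).tolist()
            declared = (pd.to_numeric(grp[cols["n_clones"]]).iloc[0]
                        if "n_clones" in cols else sum(counts))
            n_clones = int(declared)
        else:
            percents = pd.to_numeric(grp[cols["percent"]]).tolist()
            n_clones = int(pd.to_numeric(grp[cols["n_clones"]]).iloc[0])
            counts = community_diversity.counts_from_percentages(percents, n_clones)
        libraries.append(CloneLibrary(
            domain=str(domain), treatment=str(treatment), n_clones=n_clones,
            ribotypes=tuple(Ribotype(l, int(c), g) for l, c, g in zip(labels, counts, genera)),
        ))
    return libraries


def write_clone_library_table(libraries: Iterable[CloneLibrary], path: str | Path) -> None:
    rows = []
    for lib in libraries:
        for r in lib.ribotypes:
            rows.append({"domain": lib.domain, "treatment": lib.treatment,
                         "ribotype": r.label, "genus": r.genus or "",
                         "count": r.count, "n_clones": lib.n_clones})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fluid-chemistry tables
# ---------------------------------------------------------------------------

#: Default detection limits (analyte -> (limit, unit)) used when resolving
#: BDL cells of fluid tables; 0.1 mg/L for ions, 30 µM for sulfide.
DEFAULT_DETECTION_LIMITS: dict[str, tuple[float, str]] = {
    "sulfide": (30.0, "uM"),
}
_GENERIC_LIMIT = 1e-3  # nominal positive limit when no analyte-specific one is known

_CORE_FLUID_FIELDS = {"site", "Cl", "Sr", "ratio_87_86"}


def read_fluid_table(path: str | Path, bdl_policy: str = "half-limit") -> list[FluidSample]:
    """Read a fluid-chemistry table into :class:`FluidSample` records.

    ``site`` is required; ``Cl:mM``, ``Sr:uM`` and ``ratio_87_86`` populate the
    mixing tracers when present.  Every other column becomes a named analyte;
    ``BDL`` cells are resolved with :func:`handle_bdl` under ``bdl_policy`` and
    ``NA`` cells are dropped.
    """
    df = _read_table(path)
    cols = {_split_header(c)[0]: c for c in df.columns}
    _require(cols, "site")
    samples: list[FluidSample] = []
    for _, row in df.iterrows():
        def _num(name: str) -> float | None:
            if name not in cols:
                return None
            raw = str(row[cols[name]]).strip()
            if raw in NA_TOKENS or raw.upper() == BDL_TOKEN:
                return None
            return float(raw)

        analytes: dict[str, CensoredValue] = {}
        for canonical, actual in cols.items():
            if canonical in _CORE_FLUID_FIELDS:
                continue
            raw = str(row[actual]).strip()
            if raw in NA_TOKENS:
                continue
            _, unit = _split_header(actual)
            limit, lim_unit = DEFAULT_DETECTION_LIMITS.get(canonical, (_GENERIC_LIMIT, unit or ""))
            if raw.upper() != BDL_TOKEN:
                try:
                    raw = float(raw)
                except ValueError:
                    continue  # non-numeric metadata column (dates, coordinates)
            analytes[canonical] = handle_bdl(
                raw, detection_limit=limit, policy=bdl_policy, unit=unit or lim_unit,
            )
        samples.append(FluidSample(
            site=str(row[cols["site"]]), Cl_mM=_num("Cl"), Sr_uM=_num("Sr"),
            ratio_87_86=_num("ratio_87_86"), analytes=analytes,
        ))
    return samples


def write_fluid_table(samples: Iterable[FluidSample], path: str | Path) -> None:
    rows = []
    for s in samples:
        row: dict[str, object] = {"site": s.site}
        if s.Cl_mM is not None:
            row["Cl:mM"] = s.Cl_mM
        if s.Sr_uM is not None:
            row["Sr:uM"] = s.Sr_uM
        if s.ratio_87_86 is not None:
            row["ratio_87_86"] = s.ratio_87_86
        for name, cv in s.analytes.items():
            key = f"{name}:{cv.unit}" if cv.unit else name
            row[key] = BDL_TOKEN if cv.below_detection else cv.value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_ktl_fluid_fixture(bdl_policy: str = "half-limit") -> list[FluidSample]:
    """Load the packaged KTL seep fluid-chemistry table (four field samples)."""
    with resources.as_file(resources.files("seepcomm.data") / "ktl_fluids.csv") as p:
        return read_fluid_table(p, bdl_policy=bdl_policy)
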