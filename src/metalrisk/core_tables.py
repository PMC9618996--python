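"""Domain types, validation and I/O for concentration summaries and reference values.

The analysis operates on per-(species, metal) summary statistics — mean, SD and
range of the measured concentration in mg/kg dry weight — for two food classes
(vegetables and fish), together with a set of exposure constants and
toxicological reference values (MAC, RfD, CSF, MTDI, intake rates, body weight,
exposure frequency/duration). Bundled fixtures ship the study tables for 15
vegetable and 11 fish species and the default reference set.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Metal",
    "FoodClass",
    "METALS",
    "ConcentrationSummary",
    "ReferenceSet",
    "SampleMatrix",
    "SchemaError",
    "ValidationError",
    "load_concentration_table",
    "load_reference_set",
    "load_vegetables",
    "load_fish",
    "load_summaries",
    "default_reference_set",
    "summary_mean_frame",
    "write_results_table",
    "read_results_table",
]

#: relative tolerance absorbing rounding of printed summary statistics
ROUNDING_RTOL = 0.01


class Metal(str, enum.Enum):
    """The six analysed metals/metalloids, in canonical output order."""

    AS = "As"
    MN = "Mn"
    CU = "Cu"
    NI = "Ni"
    PB = "Pb"
    CR = "Cr"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


METALS: tuple[Metal, ...] = tuple(Metal)
METAL_CODES: tuple[str, ...] = tuple(m.value for m in METALS)


class FoodClass(str, enum.Enum):
    VEGETABLE = "vegetable"
    FISH = "fish"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


class ValidationError(ValueError):
    """Input parsed but failed a domain validity check."""


@dataclass(frozen=True)
class ConcentrationSummary:
    """Summary statistics of one metal in one species (mg/kg dry weight)."""

    food_class: FoodClass
    common_name: str
    scientific_name: str
    metal: Metal
    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        for name in ("mean", "sd", "min", "max"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{self.common_name}/{self.metal.value}: {name}={v!r} must be a finite non-negative number"
                )
        if self.max < self.min:
            raise ValidationError(
                f"{self.common_name}/{self.metal.value}: max {self.max} < min {self.min}"
            )
        # printed means are rounded, so allow a small relative slack
        if not (self.min <= self.mean * (1 + ROUNDING_RTOL) and self.mean <= self.max * (1 + ROUNDING_RTOL)):
            raise ValidationError(
                f"{self.common_name}/{self.metal.value}: mean {self.mean} outside [{self.min}, {self.max}]"
            )

    @property
    def species(self) -> str:
        """Unique species key (common names are unique in the fixtures)."""
        return self.common_name


@dataclass(frozen=True)
class ReferenceSet:
    """Exposure constants and toxicological reference values.

    ``mac`` and ``mtdi`` are keyed per (food class, metal) and may be absent
    for individual metals (e.g. there is no vegetable MAC for Mn); ``rfd`` is
    complete over the six metals; ``csf`` exists only for the carcinogens
    As and Pb.
    """

    mac: Mapping[tuple[FoodClass, Metal], float]
    rfd: Mapping[Metal, float]
    csf: Mapping[Metal, float]
    mtdi: Mapping[tuple[FoodClass, Metal], float]
    fir: Mapping[FoodClass, float]  # g/person/day
    bw: float  # kg
    ef: float  # days/year
    ed: float  # years
    at_days: float  # days
    mdl: Mapping[Metal, float] = field(default_factory=dict)  # mg/kg
    apli_metals: Mapping[FoodClass, tuple[Metal, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [m for m in METALS if m not in self.rfd]
        if missing:
            raise ValidationError(f"RfD missing for {[m.value for m in missing]}")
        for fc in FoodClass:
            if fc not in self.fir:
                raise ValidationError(f"FIR missing for food class {fc.value}")
        scalars = {"bw": self.bw, "ef": self.ef, "ed": self.ed, "at_days": self.at_days}
        for name, v in scalars.items():
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name}={v!r} must be positive")
        for mapping in (self.mac, self.rfd, self.csf, self.mtdi, self.fir, self.mdl):
            for key, v in mapping.items():
                if not (np.isfinite(v) and v > 0):
                    raise ValidationError(f"reference value {key!r}={v!r} must be positive")


@dataclass
class SampleMatrix:
    """A samples-by-metals concentration matrix with detection-limit flags.

    ``values`` holds working concentrations (below-detection cells may have
    been substituted); ``raw`` keeps the pre-substitution values for audit and
    for the uncertainty-equation branch condition; ``below_mdl`` marks cells
    with raw value <= the metal's MDL.
    """

    values: np.ndarray  # (n_samples, n_metals), mg/kg dw
    species: list[str]  # per-row species label
    metals: tuple[Metal, ...] = METALS
    mdl: Mapping[Metal, float] | None = None
    below_mdl: np.ndarray | None = None  # bool, same shape as values
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.metals):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with {len(self.metals)} metals"
            )
        if len(self.species) != self.values.shape[0]:
            raise ValidationError("species labels do not match the number of rows")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("concentrations must be finite and non-negative")
        if self.below_mdl is not None:
            self.below_mdl = np.asarray(self.below_mdl, dtype=bool)
            if self.below_mdl.shape != self.values.shape:
                raise ValidationError("below_mdl mask shape mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[m.value for m in self.metals])
        df.insert(0, "species", self.species)
        if self.below_mdl is not None:
            for j, m in enumerate(self.metals):
                df[f"below_mdl_{m.value}"] = self.below_mdl[:, j]
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


_SCHEMA = ["food_class", "common_name", "scientific_name", "metal", "mean", "sd", "min", "max"]


def load_concentration_table(
    path: str | Path, food_class: FoodClass | str | None = None
) -> list[ConcentrationSummary]:
    """Read a long-format concentration-summary CSV.

    One row per (species, metal). All validation failures are collected and
    reported together with their (1-based, header-inclusive) row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in _SCHEMA if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if food_class is not None:
        food_class = FoodClass(food_class)

    records: list[ConcentrationSummary] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # header is row 1
        try:
            fc = FoodClass(str(row["food_class"]))
            if food_class is not None and fc is not food_class:
                errors.append(f"row {rowno}: food_class {fc.value!r}, expected {food_class.value!r}")
                continue
            records.append(
                ConcentrationSummary(
                    food_class=fc,
                    common_name=str(row["common_name"]),
                    scientific_name=str(row["scientific_name"]),
                    metal=Metal(str(row["metal"])),
                    mean=float(row["mean"]),
                    sd=float(row["sd"]),
                    min=float(row["min"]),
                    max=float(row["max"]),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {rowno}: {exc}")
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    return records


def _data_path(name: str) -> Path:
    return Path(resources.files("metalrisk").joinpath("data", name))  # type: ignore[arg-type]


def load_vegetables() -> list[ConcentrationSummary]:
    """Bundled vegetable table: 15 species x 6 metals."""
    return load_concentration_table(_data_path("vegetables.csv"), FoodClass.VEGETABLE)


def load_fish() -> list[ConcentrationSummary]:
    """Bundled fish table: 11 species x 6 metals."""
    return load_concentration_table(_data_path("fish.csv"), FoodClass.FISH)


def load_summaries(food_class: FoodClass | str) -> list[ConcentrationSummary]:
    fc = FoodClass(food_class)
    return load_vegetables() if fc is FoodClass.VEGETABLE else load_fish()


def load_reference_set(path: str | Path | None = None) -> ReferenceSet:
    """Load a ReferenceSet from YAML; without a path, load the bundled defaults."""
    if path is None:
        path = _data_path("reference_defaults.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a mapping at top level")

    def per_class_metal(key: str) -> dict[tuple[FoodClass, Metal], float]:
        out: dict[tuple[FoodClass, Metal], float] = {}
        for fc_label, metals in raw.get(key, {}).items():
            fc = FoodClass(fc_label)
            for code, v in metals.items():
                out[(fc, Metal(code))] = float(v)
        return out

    def per_metal(key: str) -> dict[Metal, float]:
        return {Metal(code): float(v) for code, v in raw.get(key, {}).items()}

    try:
        return ReferenceSet(
            mac=per_class_metal("mac_mg_per_kg"),
            rfd=per_metal("rfd_mg_per_kg_day"),
            csf=per_metal("csf_per_mg_kg_day"),
            mtdi=per_class_metal("mtdi_mg_per_day"),
            fir={FoodClass(k): float(v) for k, v in raw["food_intake_g_per_day"].items()},
            bw=float(raw["body_weight_kg"]),
            ef=float(raw["exposure_frequency_days_per_year"]),
            ed=float(raw["exposure_duration_years"]),
            at_days=float(raw["averaging_time_days"]),
            mdl=per_metal("mdl_mg_per_kg"),
            apli_metals={
                FoodClass(k): tuple(Metal(c) for c in v)
                for k, v in raw.get("apli_metals", {}).items()
            },
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: missing key {exc}") from None


def default_reference_set() -> ReferenceSet:
    return load_reference_set(None)


def summary_mean_frame(summaries: Iterable[ConcentrationSummary]) -> pd.DataFrame:
    """Species-by-metal matrix of mean concentrations, fixture row order."""
    summaries = list(summaries)
    species: list[str] = []
    for s in summaries:
        if s.species not in species:
            species.append(s.species)
    df = pd.DataFrame(index=species, columns=METAL_CODES, dtype=float)
    for s in summaries:
        df.loc[s.species, s.metal.value] = s.mean
    if df.isna().any().any():
        missing = [(sp, m) for sp in df.index for m in df.columns if pd.isna(df.loc[sp, m])]
        raise ValidationError(f"incomplete summary set; missing {missing[:5]}...")
    df.index.name = "species"
    return df


def write_results_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a results table to CSV with 12-significant-digit round-trip fidelity."""
    if records is None or len(records) == 0:
        raise ValidationError("refusing to write an empty results table")
    records.to_csv(path, float_format="%.12g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
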