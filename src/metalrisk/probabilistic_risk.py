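"""Monte Carlo carcinogenic-risk distribution and sensitivity analysis.

Each trial draws the carcinogenic-risk inputs (C, FIR, EF, ED, BW, AT, CSF)
from configurable marginal distributions and evaluates

    TCR = C * FIR * 1e-3 * EF * ED * CSF / (BW * AT)

independently across trials. Summaries are the empirical mean, SD and 5th /
95th percentiles (linear interpolation). Sensitivity follows the
contribution-to-variance convention of risk software: the signed share of
variable v is

    sign(rho_v) * 100 * rho_v^2 / sum_w rho_w^2

with rho_v the Spearman rank correlation between the draws of v and the TCR
draws; constant (point-mass) inputs contribute 0.

The default configuration samples C empirically over the per-species mean
concentrations of the food class and gives every exposure constant a uniform
+/-20% band around its deterministic default; AT varies independently of ED
(a linked AT = 365*ED mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core_tables import (
    ConcentrationSummary,
    FoodClass,
    Metal,
    ReferenceSet,
    ValidationError,
    summary_mean_frame,
)

__all__ = ["VariableSpec", "McResult", "default_specs", "run_mc", "sensitivity"]

MC_VARIABLES = ("C", "FIR", "EF", "ED", "BW", "AT", "CSF")


@dataclass(frozen=True)
class VariableSpec:
    """Marginal distribution of one risk-equation input.

    distributions: point(value); normal(mean, sd); lognormal(mean, sd) —
    arithmetic moments; uniform(low, high); triangular(low, mode, high);
    empirical(values). Optional truncation bounds clip normal/lognormal draws
    by resampling.
    """

    name: str
    distribution: str
    params: Mapping[str, object]
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.name not in MC_VARIABLES:
            raise ValidationError(f"unknown variable {self.name!r}")
        if self.distribution not in (
            "point",
            "normal",
            "lognormal",
            "uniform",
            "triangular",
            "empirical",
        ):
            raise ValidationError(f"unknown distribution {self.distribution!r}")
        self.validate()

    def validate(self) -> None:
        p = self.params
        try:
            if self.distribution == "point":
                float(p["value"])  # type: ignore[arg-type]
            elif self.distribution in ("normal", "lognormal"):
                if float(p["sd"]) < 0:  # type: ignore[arg-type]
                    raise ValidationError(f"{self.name}: sd must be >= 0")
                if self.distribution == "lognormal" and float(p["mean"]) <= 0:  # type: ignore[arg-type]
                    raise ValidationError(f"{self.name}: lognormal mean must be > 0")
            elif self.distribution == "uniform":
                if float(p["high"]) < float(p["low"]):  # type: ignore[arg-type]
                    raise ValidationError(f"{self.name}: high < low")
            elif self.distribution == "triangular":
                lo, mode, hi = float(p["low"]), float(p["mode"]), float(p["high"])  # type: ignore[arg-type]
                if not (lo <= mode <= hi):
                    raise ValidationError(f"{self.name}: need low <= mode <= high")
            elif self.distribution == "empirical":
                vals = np.asarray(p["values"], float)  # type: ignore[arg-type]
                if vals.size == 0:
                    raise ValidationError(f"{self.name}: empirical values empty")
        except KeyError as exc:
            raise ValidationError(
                f"{self.name}/{self.distribution}: missing parameter {exc}"
            ) from None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.distribution == "point":
            return np.full(n, float(p["value"]))  # type: ignore[arg-type]
        if self.distribution == "uniform":
            return rng.uniform(float(p["low"]), float(p["high"]), size=n)  # type: ignore[arg-type]
        if self.distribution == "triangular":
            return rng.triangular(float(p["low"]), float(p["mode"]), float(p["high"]), size=n)  # type: ignore[arg-type]
        if self.distribution == "empirical":
            vals = np.asarray(p["values"], float)  # type: ignore[arg-type]
            return rng.choice(vals, size=n, replace=True)
        mean, sd = float(p["mean"]), float(p["sd"])  # type: ignore[arg-type]
        if self.distribution == "normal":
            draws = rng.normal(mean, sd, size=n)
        else:  # lognormal parameterised by arithmetic mean / sd
            if sd == 0:
                return np.full(n, mean)
            log_sd = np.sqrt(np.log1p((sd / mean) ** 2))
            log_mean = np.log(mean) - 0.5 * log_sd**2
            draws = rng.lognormal(log_mean, log_sd, size=n)
        if self.bounds is not None:
            lo, hi = self.bounds
            bad = (draws < lo) | (draws > hi)
            while np.any(bad):
                draws[bad] = (
                    rng.normal(mean, sd, size=int(bad.sum()))
                    if self.distribution == "normal"
                    else rng.lognormal(log_mean, log_sd, size=int(bad.sum()))
                )
                bad = (draws < lo) | (draws > hi)
        return draws

    @property
    def is_point(self) -> bool:
        if self.distribution == "point":
            return True
        if self.distribution in ("normal", "lognormal") and float(self.params["sd"]) == 0:  # type: ignore[arg-type]
            return True
        if self.distribution == "uniform" and float(self.params["low"]) == float(self.params["high"]):  # type: ignore[arg-type]
            return True
        if self.distribution == "empirical":
            return np.unique(np.asarray(self.params["values"], float)).size == 1  # type: ignore[arg-type]
        return False


@dataclass
class McResult:
    draws: np.ndarray
    inputs: dict[str, np.ndarray]
    mean: float
    sd: float
    p5: float
    p95: float
    sensitivity: dict[str, float]
    seed: int
    metal: Metal
    food_class: FoodClass


def default_specs(
    metal: Metal,
    food_class: FoodClass,
    summaries: Iterable[ConcentrationSummary],
    refs: ReferenceSet,
    spread: float = 0.2,
    linked_at: bool = False,
) -> dict[str, VariableSpec]:
    """Default input distributions: empirical C over species means, uniform
    +/-``spread`` bands on the exposure constants, point-mass CSF."""
    means = summary_mean_frame(summaries)[metal.value].to_numpy()
    csf = refs.csf.get(metal)
    if csf is None:
        raise ValidationError(f"no cancer slope factor for {metal.value}")

    def band(value: float) -> dict[str, float]:
        return {"low": value * (1 - spread), "high": value * (1 + spread)}

    specs = {
        "C": VariableSpec("C", "empirical", {"values": means}),
        "FIR": VariableSpec("FIR", "uniform", band(refs.fir[food_class])),
        "EF": VariableSpec("EF", "uniform", band(refs.ef)),
        "ED": VariableSpec("ED", "uniform", band(refs.ed)),
        "BW": VariableSpec("BW", "uniform", band(refs.bw)),
        "AT": VariableSpec("AT", "uniform", band(refs.at_days)),
        "CSF": VariableSpec("CSF", "point", {"value": csf}),
    }
    if linked_at:
        del specs["AT"]
    return specs


def _evaluate(inputs: Mapping[str, np.ndarray], linked_at: bool) -> np.ndarray:
    at = 365.0 * inputs["ED"] if linked_at else inputs["AT"]
    return (
        inputs["C"]
        * inputs["FIR"]
        * 1e-3
        * inputs["EF"]
        * inputs["ED"]
        * inputs["CSF"]
        / (inputs["BW"] * at)
    )


def run_mc(
    metal: Metal,
    food_class: FoodClass,
    specs: Mapping[str, VariableSpec],
    n_trials: int = 10_000,
    seed: int = 0,
    linked_at: bool = False,
) -> McResult:
    """Monte Carlo TCR distribution from independent joint draws."""
    if n_trials < 100:
        raise ValidationError("n_trials must be >= 100")
    required = set(MC_VARIABLES) - ({"AT"} if linked_at else set())
    missing = required - set(specs)
    if missing:
        raise ValidationError(f"missing variable specs: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    inputs = {name: specs[name].sample(n_trials, rng) for name in sorted(required)}
    draws = _evaluate(inputs, linked_at)
    if all(specs[n].is_point for n in inputs):
        sens = {n: 0.0 for n in inputs}  # degenerate: nothing varies
    else:
        sens = sensitivity(draws, inputs, {n: specs[n].is_point for n in inputs})
    return McResult(
        draws=draws,
        inputs=inputs,
        mean=float(draws.mean()),
        sd=float(draws.std(ddof=1)),
        p5=float(np.percentile(draws, 5)),
        p95=float(np.percentile(draws, 95)),
        sensitivity=sens,
        seed=seed,
        metal=metal,
        food_class=food_class,
    )


def sensitivity(
    draws: np.ndarray,
    inputs: Mapping[str, np.ndarray],
    is_point: Mapping[str, bool] | None = None,
) -> dict[str, float]:
    """Signed contribution-to-variance percentages from Spearman rank
    correlations; absolute values sum to 100 (0 for point-mass inputs)."""
    if np.unique(draws).size < 2:
        raise ValidationError("output is constant; sensitivity undefined")
    rho: dict[str, float] = {}
    for name, vals in inputs.items():
        if (is_point and is_point.get(name)) or np.unique(vals).size < 2:
            rho[name] = 0.0
            continue
        r = stats.spearmanr(vals, draws).statistic
        rho[name] = 0.0 if np.isnan(r) else float(r)
    total = sum(r * r for r in rho.values())
    if total == 0:
        raise ValidationError("no varying input correlates with the output")
    return {
        name: float(np.sign(r) * 100.0 * r * r / total) for name, r in rho.items()
    }
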