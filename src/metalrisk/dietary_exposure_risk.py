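"""Deterministic dietary exposure and health-risk metrics.

Estimated daily metal intake (EDI, mg/kg body weight/day):

    EDI = FIR * 1e-3 * C / BW

with FIR the food intake rate in g/person/day and C the concentration in
mg/kg. Non-carcinogenic risk per metal is the target hazard quotient

    THQ = C * FIR * EF * ED * 1e-3 / (BW * AT * RfD)

which reduces to EDI/RfD under the default exposure pattern (EF = 365
days/year, AT = 365*ED). The hazard index HI sums THQ over the six metals.
Carcinogenic risk for As and Pb is

    TCR = C * FIR * EF * ED * CSF * 1e-3 / (BW * AT)  ( = EDI * CSF )

and TTCR sums it over the two carcinogens. The 1e-3 factor converts the
intake rate from grams to kilograms.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .core_tables import (
    ConcentrationSummary,
    FoodClass,
    Metal,
    METALS,
    ReferenceSet,
    ValidationError,
    summary_mean_frame,
)

__all__ = [
    "edmi",
    "thq",
    "hazard_index",
    "tcr",
    "classify_tcr",
    "CARCINOGENS",
    "edi_table",
    "thq_table",
    "tcr_table",
    "total_edi_check",
]

CARCINOGENS: tuple[Metal, ...] = (Metal.AS, Metal.PB)

# TCR band lower bounds; a boundary value belongs to the upper band.
TCR_BANDS: tuple[tuple[float, str], ...] = (
    (0.0, "very low"),
    (1e-6, "low"),
    (1e-5, "medium"),
    (1e-4, "high"),
    (1e-3, "very high"),
)


def edmi(c: float, refs: ReferenceSet, food_class: FoodClass) -> float:
    """Estimated daily metal intake, mg/kg-bw/day."""
    if c < 0:
        raise ValidationError(f"concentration must be non-negative, got {c}")
    return refs.fir[food_class] * 1e-3 * c / refs.bw


def thq(c: float, metal: Metal, refs: ReferenceSet, food_class: FoodClass) -> float:
    """Target hazard quotient for one metal."""
    rfd = refs.rfd.get(metal)
    if rfd is None:
        raise ValidationError(f"no RfD for {metal.value}")
    return (c * refs.fir[food_class] * refs.ef * refs.ed * 1e-3) / (
        refs.bw * refs.at_days * rfd
    )


def hazard_index(thqs: Mapping[Metal, float] | Iterable[float]) -> float:
    """Hazard index: the sum of the per-metal hazard quotients."""
    values = list(thqs.values()) if isinstance(thqs, Mapping) else list(thqs)
    return float(sum(values))


def tcr(c: float, metal: Metal, refs: ReferenceSet, food_class: FoodClass) -> float:
    """Target carcinogenic risk for a carcinogen (As or Pb)."""
    csf = refs.csf.get(metal)
    if csf is None:
        raise ValidationError(f"no cancer slope factor for {metal.value}")
    return (c * refs.fir[food_class] * refs.ef * refs.ed * csf * 1e-3) / (
        refs.bw * refs.at_days
    )


def classify_tcr(value: float) -> str:
    """Five-band carcinogenic-risk label."""
    if value < 0:
        raise ValidationError(f"TCR must be non-negative, got {value}")
    label = TCR_BANDS[0][1]
    for lower, name in TCR_BANDS:
        if value >= lower:
            label = name
    return label


def _mean_frame(summaries: Iterable[ConcentrationSummary]) -> tuple[pd.DataFrame, FoodClass]:
    summaries = list(summaries)
    if not summaries:
        raise ValidationError("no summaries supplied")
    fc = summaries[0].food_class
    if any(s.food_class is not fc for s in summaries):
        raise ValidationError("summaries must share one food class")
    return summary_mean_frame(summaries), fc


def edi_table(
    summaries: Iterable[ConcentrationSummary], refs: ReferenceSet
) -> pd.DataFrame:
    """Species-by-metal EDI table with a Total row."""
    means, fc = _mean_frame(summaries)
    out = means.apply(lambda col: col.map(lambda c: edmi(c, refs, fc)))
    out.loc["Total"] = out.sum(axis=0)
    return out


def thq_table(
    summaries: Iterable[ConcentrationSummary], refs: ReferenceSet
) -> pd.DataFrame:
    """Species-by-metal THQ table with hazard index column and Total row."""
    means, fc = _mean_frame(summaries)
    out = pd.DataFrame(index=means.index, dtype=float)
    for m in METALS:
        out[m.value] = means[m.value].map(lambda c, m=m: thq(c, m, refs, fc))
    out["HI"] = out[[m.value for m in METALS]].sum(axis=1)
    out.loc["Total"] = out.sum(axis=0)
    return out


def tcr_table(
    summaries: Iterable[ConcentrationSummary], refs: ReferenceSet
) -> pd.DataFrame:
    """Per-species TCR for As and Pb, their total (TTCR), and band labels."""
    means, fc = _mean_frame(summaries)
    out = pd.DataFrame(index=means.index, dtype=float)
    for m in CARCINOGENS:
        out[m.value] = means[m.value].map(lambda c, m=m: tcr(c, m, refs, fc))
    out["TTCR"] = out[[m.value for m in CARCINOGENS]].sum(axis=1)
    bands = {
        f"band_{m.value}": out[m.value].map(classify_tcr) for m in CARCINOGENS
    }
    out.loc["Total"] = out[[m.value for m in CARCINOGENS] + ["TTCR"]].sum(axis=0)
    for name, col in bands.items():
        out[name] = col
    return out


def total_edi_check(
    summaries: Iterable[ConcentrationSummary], refs: ReferenceSet
) -> pd.DataFrame:
    """Per-metal EDI column totals compared against the MTDI.

    The comparison is made on the numbers as tabulated (EDI total against the
    MTDI row), matching the published screening.
    """
    means, fc = _mean_frame(summaries)
    totals = edi_table(summaries, refs).loc["Total"]
    rows = []
    for m in METALS:
        mtdi = refs.mtdi.get((fc, m))
        rows.append(
            {
                "metal": m.value,
                "total_edi": totals[m.value],
                "mtdi_mg_per_day": mtdi,
                "below_mtdi": (totals[m.value] < mtdi) if mtdi is not None else None,
            }
        )
    return pd.DataFrame(rows).set_index("metal")
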