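"""Average pollution load index (APLI) and pollution-category labelling.

For a species with mean concentrations C_i and maximum allowable
concentrations S_i, APLI = (1/n) * sum_i C_i / S_i over the metals that carry
a usable MAC. By default Mn is excluded for both food classes: vegetables
have no Mn MAC at all, and the published fish index values are only
consistent with the Mn ratio left out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core_tables import (
    ConcentrationSummary,
    FoodClass,
    Metal,
    ReferenceSet,
    ValidationError,
)

__all__ = ["ApliResult", "apli", "apli_table", "classify_pollution", "CATEGORIES"]

# [lower bound, label); the last band is open-ended. Boundaries belong to the
# upper band.
CATEGORIES: tuple[tuple[float, str], ...] = (
    (0.0, "unpolluted"),
    (0.1, "micro pollution"),
    (0.2, "lightly polluted"),
    (0.5, "moderately polluted"),
    (0.7, "heavily polluted"),
    (1.0, "seriously polluted"),
)


@dataclass(frozen=True)
class ApliResult:
    species: str
    food_class: FoodClass
    value: float
    n_metals_used: int
    category: str


def classify_pollution(value: float) -> str:
    """Map an index value to its six-bin pollution category."""
    if value < 0:
        raise ValidationError(f"pollution index must be non-negative, got {value}")
    label = CATEGORIES[0][1]
    for lower, name in CATEGORIES:
        if value >= lower:
            label = name
    return label


def apli(
    summaries: Iterable[ConcentrationSummary],
    refs: ReferenceSet,
    metals: Sequence[Metal] | None = None,
) -> ApliResult:
    """Compute the index for one species from its six summary records.

    ``metals`` overrides the metal subset; by default the reference set's
    configured subset (or every metal with a MAC) is used.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValidationError("no summaries supplied")
    species = summaries[0].species
    fc = summaries[0].food_class
    if any(s.species != species or s.food_class is not fc for s in summaries):
        raise ValidationError("apli expects records for a single species")

    if metals is None:
        metals = refs.apli_metals.get(fc) or tuple(
            m for m in Metal if (fc, m) in refs.mac
        )
    ratios = []
    for s in summaries:
        if s.metal in metals:
            mac = refs.mac.get((fc, s.metal))
            if mac is None:
                raise ValidationError(
                    f"{species}: no MAC for {s.metal.value} ({fc.value})"
                )
            ratios.append(s.mean / mac)
    if not ratios:
        raise ValidationError(f"{species}: no usable MAC among requested metals")
    value = sum(ratios) / len(ratios)
    return ApliResult(
        species=species,
        food_class=fc,
        value=value,
        n_metals_used=len(ratios),
        category=classify_pollution(value),
    )


def apli_table(
    summaries: Iterable[ConcentrationSummary], refs: ReferenceSet
) -> pd.DataFrame:
    """Per-species index table in fixture order."""
    by_species: dict[str, list[ConcentrationSummary]] = {}
    for s in summaries:
        by_species.setdefault(s.species, []).append(s)
    rows = []
    for species, recs in by_species.items():
        r = apli(recs, refs)
        rows.append(
            {
                "species": species,
                "food_class": r.food_class.value,
                "apli": r.value,
                "n_metals_used": r.n_metals_used,
                "category": r.category,
            }
        )
    return pd.DataFrame(rows).set_index("species")
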