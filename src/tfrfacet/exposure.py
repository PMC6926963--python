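"""Ingredient-resolved chronic exposure: daily dose and hazard index.

A composite food's daily consumption rate CR (g/day, per population stratum)
is decomposed into ingredient-group consumption using the facet weight
percentages, and each share is screened against an oral reference dose:

    ADD = C × (CR / 1000) / BW        [mg contaminant / kg body weight / day]
    HI  = ADD / RfD                   [dimensionless; HI > 1 flags concern]

where C is the contaminant concentration in the food (mg/kg), BW the stratum
body weight (kg) and RfD the chronic oral reference dose (mg/kg-bw/day).
The division by 1000 converts CR from grams to kilograms of food; it is part
of the implemented formula even though dose equations are often written
without it, because the quantities are conventionally tabulated in those
units.  Internal computation is never rounded; report rounding (CR to 2
decimals, ADD to 6, HI to 2, half-up) is applied only at the formatting
layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "ADD_FORMULA",
    "Stratum",
    "ConsumptionRecord",
    "Contaminant",
    "ExposureResult",
    "COMPOSITE_GROUP",
    "round_half_up",
    "decompose_cr",
    "average_daily_dose",
    "hazard_index",
    "assess",
    "results_to_frame",
    "report_frame",
]

ADD_FORMULA = "ADD [mg/kg-bw/day] = C [mg/kg] x (CR [g/day] / 1000) / BW [kg]"

#: Group label used for the per-(stratum, food) composite row.
COMPOSITE_GROUP = "total"


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (the convention behind the report tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Stratum:
    """A population stratum (e.g. male / female / mean, ages 19–65)."""

    label: str
    body_weight_kg: float

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0:
            raise ValueError(
                f"stratum {self.label!r}: body weight must be > 0 kg"
            )


@dataclass(frozen=True)
class ConsumptionRecord:
    stratum: str
    food_code: str
    cr_g_per_day: float

    def __post_init__(self) -> None:
        if self.cr_g_per_day < 0:
            raise ValueError(
                f"consumption rate for ({self.stratum}, {self.food_code}) "
                "must be >= 0"
            )


@dataclass(frozen=True)
class Contaminant:
    """A contaminant with a whole-food concentration and oral RfD.

    ``concentration_by_group`` optionally overrides the scalar concentration
    per reporting group.
    """

    name: str
    concentration_mg_per_kg: float
    rfd_mg_per_kg_day: float
    provenance: str = ""
    concentration_by_group: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.concentration_mg_per_kg < 0:
            raise ValueError("concentration must be >= 0")
        if self.rfd_mg_per_kg_day <= 0:
            raise ValueError("reference dose must be > 0")

    def concentration_for(self, group: str) -> float:
        if self.concentration_by_group is not None:
            try:
                return self.concentration_by_group[group]
            except KeyError:
                raise KeyError(
                    f"no concentration configured for group {group!r}"
                ) from None
        return self.concentration_mg_per_kg


@dataclass(frozen=True)
class ExposureResult:
    stratum: str
    food_code: str
    group: str
    cr_g_per_day: float
    add_mg_per_kg_day: float
    hi: float
    exceeds_threshold: bool


def decompose_cr(cr_food: float, pct: float) -> float:
    """Ingredient-group consumption: food CR times the group's weight share."""
    if cr_food < 0:
        raise ValueError("consumption rate must be >= 0")
    if not 0.0 <= pct <= 1.0:
        raise ValueError(f"percentage {pct} outside [0, 1]")
    return cr_food * pct


def average_daily_dose(c: float, cr: float, bw: float) -> float:
    """ADD in mg/kg-bw/day from C (mg/kg), CR (g/day) and BW (kg)."""
    if bw <= 0:
        raise ValueError("body weight must be > 0")
    if c < 0 or cr < 0:
        raise ValueError("concentration and consumption must be >= 0")
    return c * (cr / 1000.0) / bw


def hazard_index(add: float, rfd: float) -> float:
    """HI = ADD / RfD; values above 1 indicate exposure of concern."""
    if rfd <= 0:
        raise ValueError("reference dose must be > 0")
    if add < 0:
        raise ValueError("dose must be >= 0")
    return add / rfd


def assess(
    consumption: Sequence[ConsumptionRecord],
    facet: Sequence["FacetWeightRow"],
    contaminant: Contaminant,
    strata: Sequence[Stratum],
) -> list[ExposureResult]:
    """Full ingredient-resolved assessment.

    Produces one result per (stratum, food, group) — decomposed CR, ADD and
    HI — plus one composite row per (stratum, food) whose quantities are the
    sums of the unrounded group quantities.  Missing facet rows or body
    weights raise ``KeyError`` naming the offending key.
    """
    bw = {s.label: s.body_weight_kg for s in strata}
    pct_by_food: dict[str, dict[str, float]] = {}
    for row in facet:
        pct_by_food.setdefault(row.food_code, {})[row.group] = row.pct

    results: list[ExposureResult] = []
    for rec in consumption:
        if rec.stratum not in bw:
            raise KeyError(
                f"no body weight configured for stratum {rec.stratum!r}"
            )
        if rec.food_code not in pct_by_food:
            raise KeyError(
                f"no facet weight rows for food code {rec.food_code!r}"
            )
        body_weight = bw[rec.stratum]
        total_cr = total_add = total_hi = 0.0
        for group, pct in pct_by_food[rec.food_code].items():
            cr_g = decompose_cr(rec.cr_g_per_day, pct)
            add = average_daily_dose(
                contaminant.concentration_for(group), cr_g, body_weight
            )
            hi = hazard_index(add, contaminant.rfd_mg_per_kg_day)
            results.append(
                ExposureResult(
                    rec.stratum, rec.food_code, group, cr_g, add, hi, hi > 1
                )
            )
            total_cr += cr_g
            total_add += add
            total_hi += hi
        results.append(
            ExposureResult(
                rec.stratum,
                rec.food_code,
                COMPOSITE_GROUP,
                total_cr,
                total_add,
                total_hi,
                total_hi > 1,
            )
        )
    return results


def results_to_frame(results: Sequence[ExposureResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stratum": [r.stratum for r in results],
            "food_code": [r.food_code for r in results],
            "group": [r.group for r in results],
            "cr_g_per_day": [r.cr_g_per_day for r in results],
            "add_mg_per_kg_day": [r.add_mg_per_kg_day for r in results],
            "hi": [r.hi for r in results],
            "exceeds_threshold": [r.exceeds_threshold for r in results],
        }
    )


def report_frame(
    results: Sequence[ExposureResult],
    rounding: str = "standard",
) -> pd.DataFrame:
    """Rounded report table: CR to 2 decimals, ADD to 6, HI to 2 (half-up).

    ``rounding="legacy"`` reports each composite row's HI as the sum of its
    *rounded* group HIs — the convention some published summary tables
    follow — instead of rounding the unrounded sum.
    """
    if rounding not in ("standard", "legacy"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    df = results_to_frame(results)
    out = df.copy()
    out["cr_g_per_day"] = df["cr_g_per_day"].map(lambda x: round_half_up(x, 2))
    out["add_mg_per_kg_day"] = df["add_mg_per_kg_day"].map(
        lambda x: round_half_up(x, 6)
    )
    out["hi"] = df["hi"].map(lambda x: round_half_up(x, 2))
    if rounding == "legacy":
        rounded_groups = out[out["group"] != COMPOSITE_GROUP]
        legacy = rounded_groups.groupby(["stratum", "food_code"])["hi"].sum()
        mask = out["group"] == COMPOSITE_GROUP
        out.loc[mask, "hi"] = [
            round_half_up(legacy[(s, f)], 2)
            for s, f in zip(out.loc[mask, "stratum"], out.loc[mask, "food_code"])
        ]
    return out
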