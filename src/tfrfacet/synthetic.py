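"""Synthetic recipe corpora and consumption tables with known ground truth.

Every stage of the pipeline is testable offline: the generator emits recipe
and consumption files in the exact schemas the readers expect, together
with a ground-truth table of the true per-group mean weights and
percentages, so recovery tests never reverse-engineer the truth from the
data.

Group weights are lognormal by default — dish weights are positive and
right-skewed, with occasional recipes several times larger than the mean —
parameterized directly by the target mean and SD in grams (moment
matching).  A normal family truncated at zero is available for tests that
need approximate normality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .codes import HfdfcCode
from .exposure import ConsumptionRecord, Stratum
from .recipes import Ingredient, Recipe, descriptor_from_sub_code

__all__ = [
    "GroupSpec",
    "FoodSpec",
    "StratumSpec",
    "SyntheticSpec",
    "generate_recipes",
    "generate_consumption",
    "rice_study_spec",
]

# Ingredient name pool per descriptor sub-code, drawn from the default
# lexicon so generated files pass classification unchanged.
_NAME_POOL: dict[int, tuple[str, ...]] = {
    1: ("rice", "flour", "noodles"),
    2: ("water",),
    3: ("tofu", "soybean"),
    4: ("salmon", "tuna", "swordfish", "anchovy larvae", "shrimp"),
    5: ("egg",),
    6: ("pork", "beef", "chicken"),
    7: ("milk",),
    8: ("cabbage", "cucumber", "tomato", "lettuce", "sweet pepper", "carrot"),
    9: ("avocado",),
    10: ("peanut", "sesame"),
    11: ("sesame oil", "lard", "vegetable oil"),
    12: ("tea",),
    13: ("rice wine",),
    14: ("salt", "soy sauce", "mustard", "sugar"),
}


@dataclass(frozen=True)
class GroupSpec:
    """Target distribution of one reporting group's cooked weight."""

    sub_codes: tuple[int, ...]
    mean_g: float
    sd_g: float
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.mean_g <= 0:
            raise ValueError("group mean weight must be > 0 g")
        if self.sd_g < 0:
            raise ValueError("group weight SD must be >= 0")
        if self.family not in ("lognormal", "normal"):
            raise ValueError(f"unknown weight family {self.family!r}")
        if not self.sub_codes:
            raise ValueError("group needs at least one descriptor sub-code")


@dataclass(frozen=True)
class FoodSpec:
    food_code: str
    n_recipes: int
    groups: dict[str, GroupSpec]

    def __post_init__(self) -> None:
        HfdfcCode(self.food_code)  # validate
        if self.n_recipes < 1:
            raise ValueError("recipes_per_food must be >= 1")


@dataclass(frozen=True)
class StratumSpec:
    """Body weight plus per-food consumption-rate distribution.

    ``cr_sd_g`` of zero gives a point mass (a published per-capita rate);
    positive values draw from a zero-truncated normal.
    """

    label: str
    body_weight_kg: float
    cr_mean_g: dict[str, float]
    cr_sd_g: float = 0.0

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be > 0")
        if self.cr_sd_g < 0:
            raise ValueError("consumption SD must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    foods: tuple[FoodSpec, ...]
    strata: tuple[StratumSpec, ...] = ()
    cooked_over_raw: float = 2.3  # cooking-yield ratio applied to all groups
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.foods:
            raise ValueError("at least one food is required")
        if self.cooked_over_raw <= 0:
            raise ValueError("cooked/raw ratio must be > 0")

    @classmethod
    def uniform(
        cls,
        n_foods: int,
        recipes_per_food: int,
        groups: dict[str, GroupSpec],
        **kwargs,
    ) -> "SyntheticSpec":
        """Identical group structure for ``n_foods`` auto-coded foods."""
        foods = tuple(
            FoodSpec(f"O01{i + 1:04d}", recipes_per_food, dict(groups))
            for i in range(n_foods)
        )
        return cls(foods=foods, **kwargs)


def _draw_group_weights(
    rng: np.random.Generator, spec: GroupSpec, n: int
) -> np.ndarray:
    if spec.sd_g == 0:
        return np.full(n, spec.mean_g)
    if spec.family == "lognormal":
        cv2 = (spec.sd_g / spec.mean_g) ** 2
        sigma2 = np.log1p(cv2)
        mu = np.log(spec.mean_g) - sigma2 / 2
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)
    draws = rng.normal(spec.mean_g, spec.sd_g, size=n)
    return np.clip(draws, 0.0, None)


def generate_recipes(
    spec: SyntheticSpec,
) -> tuple[list[Recipe], pd.DataFrame]:
    """Generate a recipe corpus and its ground-truth table.

    Deterministic for a fixed ``spec.seed``.  The ground truth holds the
    *specified* per-group mean weights and the analytic percentages
    ``mean_g / Σ mean_g`` — never statistics of the realized sample.
    """
    rng = np.random.default_rng(spec.seed)
    recipes: list[Recipe] = []
    truth_rows = []
    for food in spec.foods:
        total_mean = sum(g.mean_g for g in food.groups.values())
        for label, gspec in food.groups.items():
            truth_rows.append(
                {
                    "food_code": food.food_code,
                    "group": label,
                    "true_mean_g": gspec.mean_g,
                    "true_pct": gspec.mean_g / total_mean,
                }
            )
        group_weights = {
            label: _draw_group_weights(rng, gspec, food.n_recipes)
            for label, gspec in food.groups.items()
        }
        for k in range(food.n_recipes):
            ingredients = []
            for label, gspec in food.groups.items():
                cooked_total = float(group_weights[label][k])
                subs = gspec.sub_codes
                shares = (
                    rng.dirichlet(np.ones(len(subs)))
                    if len(subs) > 1
                    else np.ones(1)
                )
                for sub, share in zip(subs, shares):
                    cooked = cooked_total * float(share)
                    pool = _NAME_POOL[sub]
                    name = pool[int(rng.integers(len(pool)))]
                    ingredients.append(
                        Ingredient(
                            name,
                            descriptor_from_sub_code(sub),
                            raw_weight_g=cooked / spec.cooked_over_raw,
                            cooked_weight_g=cooked,
                        )
                    )
            recipes.append(
                Recipe(
                    HfdfcCode(food.food_code),
                    f"{food.food_code}-r{k + 1:03d}",
                    tuple(ingredients),
                    source="synthetic",
                )
            )
    return recipes, pd.DataFrame(truth_rows)


def generate_consumption(spec: SyntheticSpec) -> list[ConsumptionRecord]:
    """Per-stratum consumption records; deterministic for a fixed seed."""
    # Independent stream so recipe and consumption draws do not interact.
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    records = []
    for stratum in spec.strata:
        for food in spec.foods:
            mean_cr = stratum.cr_mean_g.get(food.food_code)
            if mean_cr is None:
                raise KeyError(
                    f"stratum {stratum.label!r} has no consumption mean for "
                    f"food {food.food_code!r}"
                )
            if stratum.cr_sd_g == 0:
                cr = mean_cr
            else:
                cr = float(
                    np.clip(rng.normal(mean_cr, stratum.cr_sd_g), 0.0, None)
                )
            records.append(ConsumptionRecord(stratum.label, food.food_code, cr))
    return records


def strata_of(spec: SyntheticSpec) -> list[Stratum]:
    return [Stratum(s.label, s.body_weight_kg) for s in spec.strata]


def rice_study_spec(seed: int = 0) -> SyntheticSpec:
    """The packaged rice-dish study conditions.

    Three rice-based composite foods with the corpus sizes of the study
    (6 fried-rice, 31 sushi and 79 rice-ball recipes), lognormal group
    weights moment-matched to the published adjusted-weight summaries, and
    point-mass per-capita consumption rates for the male/female/mean adult
    strata.
    """
    foods = (
        FoodSpec(
            "O010301",
            6,
            {
                "rice": GroupSpec((1,), 176.53, 62.41),
                "other": GroupSpec((4, 5, 6, 8, 14), 92.35, 54.22),
            },
        ),
        FoodSpec(
            "O010302",
            31,
            {
                "rice": GroupSpec((1,), 77.23, 25.17),
                "other": GroupSpec((4, 6, 8, 9, 14), 100.13, 29.75),
            },
        ),
        FoodSpec(
            "O010303",
            79,
            {
                "rice": GroupSpec((1,), 461.07, 238.07),
                "other": GroupSpec((4, 6, 8, 14), 790.04, 433.96),
            },
        ),
    )
    strata = (
        StratumSpec(
            "male",
            69.33,
            {"O010301": 158.48, "O010302": 204.49, "O010303": 181.86},
        ),
        StratumSpec(
            "female",
            57.27,
            {"O010301": 93.63, "O010302": 124.64, "O010303": 195.81},
        ),
        StratumSpec(
            "mean",
            63.3,
            {"O010301": 127.5, "O010302": 177.87, "O010303": 188.06},
        ),
    )
    return SyntheticSpec(foods=foods, strata=strata, seed=seed)
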