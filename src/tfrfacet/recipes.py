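"""Recipes of composite foods and ingredient classification.

A composite food (fried rice, sushi, a rice ball) is represented by one or
more :class:`Recipe` objects, each a list of ingredients with raw and cooked
weights in grams.  Free-text ingredient names are classified into the
fourteen recipe-facet descriptors through a :class:`Lexicon` — an exact
lookup on normalized names, never fuzzy: misclassification risk is traded
for auditable, deterministic behaviour, and unknown names surface as errors
(strict mode) rather than silent guesses.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .codes import (
    CombinedCode,
    HfdfcCode,
    TfrDescriptor,
    descriptor_from_sub_code,
)

__all__ = [
    "Ingredient",
    "Recipe",
    "Lexicon",
    "ClassificationError",
    "GroupMap",
    "normalize_name",
    "classify_ingredient",
    "derive_combined_code",
    "aggregate_by_descriptor",
    "default_lexicon",
    "default_group_map",
]

_WS = re.compile(r"\s+")


class ClassificationError(KeyError):
    """An ingredient name not covered by the lexicon (strict mode)."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep message plain
        return self.args[0] if self.args else ""


def normalize_name(name: str) -> str:
    """Case-fold, trim, and collapse internal whitespace."""
    return _WS.sub(" ", name.strip()).casefold()


@dataclass(frozen=True)
class Lexicon:
    """Mapping from normalized ingredient name to descriptor sub-code."""

    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {n: s for n, s in self.entries.items() if not 1 <= s <= 14}
        if bad:
            raise ValueError(f"lexicon sub-codes outside 1-14: {bad}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "Lexicon":
        return cls({normalize_name(n): int(s) for n, s in pairs})

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self.entries


def classify_ingredient(
    name: str,
    lexicon: Lexicon,
    *,
    fallback: TfrDescriptor | None = None,
) -> TfrDescriptor:
    """Classify a free-text ingredient name.

    Strict by default: an unknown name raises :class:`ClassificationError`
    naming it.  Pass ``fallback`` for lenient mode (noisy scraped recipes).
    """
    if not lexicon.entries:
        raise ValueError("empty lexicon")
    sub = lexicon.entries.get(normalize_name(name))
    if sub is None:
        if fallback is not None:
            return fallback
        raise ClassificationError(
            f"ingredient {name!r} not in lexicon (strict mode)"
        )
    return descriptor_from_sub_code(sub)


@dataclass(frozen=True)
class Ingredient:
    name: str
    descriptor: TfrDescriptor
    raw_weight_g: float
    cooked_weight_g: float

    def __post_init__(self) -> None:
        for label, w in (
            ("raw", self.raw_weight_g),
            ("cooked", self.cooked_weight_g),
        ):
            if not math.isfinite(w) or w < 0:
                raise ValueError(
                    f"ingredient {self.name!r}: {label} weight {w!r} must be "
                    "finite and non-negative"
                )


@dataclass(frozen=True)
class Recipe:
    food_code: HfdfcCode
    recipe_id: str
    ingredients: tuple[Ingredient, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.ingredients:
            raise ValueError(f"recipe {self.recipe_id!r} has no ingredients")
        object.__setattr__(self, "ingredients", tuple(self.ingredients))
        if self.total_cooked_g <= 0:
            raise ValueError(
                f"recipe {self.recipe_id!r}: total cooked weight must be > 0"
            )

    @property
    def total_raw_g(self) -> float:
        return sum(i.raw_weight_g for i in self.ingredients)

    @property
    def total_cooked_g(self) -> float:
        return sum(i.cooked_weight_g for i in self.ingredients)


def derive_combined_code(recipes: Iterable[Recipe]) -> CombinedCode:
    """Derive a food's combined code from its recipes.

    The descriptor set is the union of descriptors appearing in any recipe
    of the food, in ascending sub-code order; all recipes must share one
    food code.
    """
    recipes = list(recipes)
    if not recipes:
        raise ValueError("empty recipe list")
    codes = {r.food_code for r in recipes}
    if len(codes) != 1:
        raise ValueError(
            "mixed food codes: " + ", ".join(sorted(c.text for c in codes))
        )
    subs = sorted(
        {i.descriptor.sub_code for r in recipes for i in r.ingredients}
    )
    return CombinedCode(
        recipes[0].food_code,
        tuple(descriptor_from_sub_code(s) for s in subs),
    )


def aggregate_by_descriptor(
    recipe: Recipe,
) -> dict[int, tuple[float, float]]:
    """Per-descriptor ``(raw_sum_g, cooked_sum_g)`` over a recipe.

    Descriptors absent from the recipe are absent from the mapping; sums
    over the mapping equal the recipe totals.
    """
    out: dict[int, tuple[float, float]] = {}
    for ing in recipe.ingredients:
        raw, cooked = out.get(ing.descriptor.sub_code, (0.0, 0.0))
        out[ing.descriptor.sub_code] = (
            raw + ing.raw_weight_g,
            cooked + ing.cooked_weight_g,
        )
    return out


@dataclass(frozen=True)
class GroupMap:
    """A partition of the 14 descriptor sub-codes into reporting groups.

    The default partition mirrors rice-dish reporting: group ``rice`` is
    {whole grains} and group ``other`` is everything else.  Groups must be
    disjoint; a sub-code encountered outside the partition is an error.
    """

    groups: Mapping[str, frozenset[int]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "groups",
            {k: frozenset(v) for k, v in self.groups.items()},
        )
        seen: set[int] = set()
        for label, subs in self.groups.items():
            if not subs:
                raise ValueError(f"group {label!r} is empty")
            bad = [s for s in subs if not 1 <= s <= 14]
            if bad:
                raise ValueError(f"group {label!r}: sub-codes {bad} outside 1-14")
            if seen & subs:
                raise ValueError(
                    f"group {label!r} overlaps another group on {sorted(seen & subs)}"
                )
            seen |= subs
        object.__setattr__(self, "_lookup", {
            s: label for label, subs in self.groups.items() for s in subs
        })

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.groups)

    def group_of(self, sub_code: int) -> str:
        try:
            return self._lookup[sub_code]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(
                f"descriptor sub-code {sub_code} not covered by the group map"
            ) from None


def default_group_map() -> GroupMap:
    """{rice} vs all other sub-descriptions — the two-column reporting split."""
    return GroupMap({"rice": frozenset({1}), "other": frozenset(range(2, 15))})


# The shipped default lexicon lives in data/lexicon.csv; loading it here
# avoids a circular import with the io module.
def default_lexicon() -> Lexicon:
    """The packaged ingredient-name lexicon."""
    from importlib.resources import files

    import pandas as pd

    with files("tfrfacet.data").joinpath("lexicon.csv").open("rb") as fh:
        df = pd.read_csv(fh)
    return Lexicon.from_pairs(zip(df["name"], df["sub_code"]))
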