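"""Monte Carlo estimation of per-group adjusted weights across recipes.

For each composite food, the weight of each reporting group (e.g. rice vs
all other ingredients) varies from recipe to recipe.  The adjusted weight is
summarized over ``n_iter`` Monte Carlo iterations (default 10,000); the
default *empirical* strategy draws one recipe uniformly with replacement per
iteration and records its per-group aggregated weight, so the simulated
distribution is the empirical recipe distribution itself — its max never
exceeds the largest per-recipe group weight, and its mean converges to the
recipe-sample mean.  Two alternatives are provided: *bootstrap-mean* (each
iteration is the mean of a resample of size ``n_recipes``, i.e. the sampling
distribution of the mean) and *lognormal* (a moment-matched parametric fit
per group).

Group percentages are computed from group means, ``pct(g) = mean_g /
Σ mean_g'`` — not as the mean of per-recipe ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .recipes import GroupMap, Recipe, aggregate_by_descriptor

__all__ = [
    "STRATEGIES",
    "WeightSummary",
    "FacetWeightRow",
    "recipe_group_weights",
    "simulate_weights",
    "group_percentages",
    "build_facet_table",
    "facet_table_to_frame",
]

STRATEGIES = ("empirical", "bootstrap-mean", "lognormal")

#: z-quantile at 0.90; under approximate normality q90 ≈ mean + Z90 * sd.
Z90 = 1.2816


@dataclass(frozen=True)
class WeightSummary:
    """Monte Carlo summary of one group's adjusted weight (grams)."""

    mean_g: float
    sd_g: float
    max_g: float
    q90_g: float
    n_iter: int
    seed: int | None
    strategy: str = "empirical"

    def __post_init__(self) -> None:
        if self.sd_g < 0:
            raise ValueError("sd_g must be >= 0")
        if self.max_g + 1e-9 < self.q90_g:
            raise ValueError("max_g must be >= q90_g")


@dataclass(frozen=True)
class FacetWeightRow:
    """One (food, group) row of the facet weight table."""

    food_code: str
    group: str
    summary: WeightSummary
    pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct <= 1.0 + 1e-12:
            raise ValueError(f"pct {self.pct} outside [0, 1]")


def recipe_group_weights(
    recipe: Recipe, group_map: GroupMap, basis: str = "cooked"
) -> dict[str, float]:
    """Aggregate one recipe's ingredient weights into reporting groups.

    Every group of the map is present in the result (0.0 when the recipe
    has no ingredient in it).
    """
    if basis not in ("cooked", "raw"):
        raise ValueError(f"unknown weight basis {basis!r}")
    out = {label: 0.0 for label in group_map.labels}
    for sub, (raw, cooked) in aggregate_by_descriptor(recipe).items():
        out[group_map.group_of(sub)] += cooked if basis == "cooked" else raw
    return out


def _weight_matrix(
    recipes: Sequence[Recipe], group_map: GroupMap, basis: str
) -> np.ndarray:
    rows = [recipe_group_weights(r, group_map, basis) for r in recipes]
    return np.array(
        [[row[g] for g in group_map.labels] for row in rows], dtype=float
    )


def simulate_weights(
    recipes: Sequence[Recipe],
    group_map: GroupMap,
    n_iter: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    strategy: str = "empirical",
    basis: str = "cooked",
) -> dict[str, WeightSummary]:
    """Monte Carlo per-group weight summaries for one food's recipes.

    Deterministic for fixed ``(recipes, seed, n_iter, strategy, basis)``.
    SD is the sample standard deviation over the draws and the 90th
    percentile uses linear interpolation.
    """
    recipes = list(recipes)
    if not recipes:
        raise ValueError("empty recipe list")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if strategy not in STRATEGIES:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected one of {STRATEGIES}"
        )
    if seed is None:
        raise ValueError("a seed must be supplied explicitly")

    weights = _weight_matrix(recipes, group_map, basis)  # (n_recipes, n_groups)
    rng = np.random.default_rng(seed)
    n = len(recipes)

    if strategy == "empirical":
        draws = weights[rng.integers(0, n, size=n_iter)]
    elif strategy == "bootstrap-mean":
        idx = rng.integers(0, n, size=(n_iter, n))
        draws = weights[idx].mean(axis=1)
    else:  # lognormal, moment-matched per group
        means = weights.mean(axis=0)
        sds = weights.std(axis=0, ddof=1) if n > 1 else np.zeros_like(means)
        # groups absent from every recipe stay identically zero
        pos = means > 0
        cv2 = np.zeros_like(means)
        cv2[pos] = (sds[pos] / means[pos]) ** 2
        sigma2 = np.log1p(cv2)
        mu = np.where(pos, np.log(np.where(pos, means, 1.0)) - sigma2 / 2, 0.0)
        draws = rng.lognormal(
            mean=mu, sigma=np.sqrt(sigma2), size=(n_iter, len(means))
        )
        draws[:, ~pos] = 0.0

    seed_out = seed if isinstance(seed, int) else None
    out: dict[str, WeightSummary] = {}
    for j, label in enumerate(group_map.labels):
        col = draws[:, j]
        out[label] = WeightSummary(
            mean_g=float(col.mean()),
            sd_g=float(col.std(ddof=1)) if n_iter > 1 else 0.0,
            max_g=float(col.max()),
            q90_g=float(np.percentile(col, 90)),
            n_iter=n_iter,
            seed=seed_out,
            strategy=strategy,
        )
    return out


def group_percentages(
    summaries: Mapping[str, WeightSummary] | Mapping[str, float],
) -> dict[str, float]:
    """Fraction of the total mean weight carried by each group.

    Accepts either summaries or plain group means.  Fractions sum to 1.
    """
    means = {
        g: (s.mean_g if isinstance(s, WeightSummary) else float(s))
        for g, s in summaries.items()
    }
    total = sum(means.values())
    if total <= 0:
        raise ValueError("all group means are zero; percentages undefined")
    if any(m < 0 for m in means.values()):
        raise ValueError("negative group mean")
    return {g: m / total for g, m in means.items()}


def build_facet_table(
    recipes: Iterable[Recipe],
    group_map: GroupMap,
    n_iter: int = 10_000,
    seed: int | None = None,
    strategy: str = "empirical",
    basis: str = "cooked",
) -> list[FacetWeightRow]:
    """Simulate every food in a recipe corpus and assemble the weight table.

    Recipes are grouped by food code (sorted, so output order is stable) and
    each food gets an independent child stream of the supplied seed.  Rows
    record the parent seed and ``n_iter`` for reproducibility.
    """
    if seed is None:
        raise ValueError("a seed must be supplied explicitly")
    by_food: dict[str, list[Recipe]] = {}
    for r in recipes:
        by_food.setdefault(r.food_code.text, []).append(r)
    if not by_food:
        raise ValueError("empty recipe list")

    children = np.random.SeedSequence(seed).spawn(len(by_food))
    rows: list[FacetWeightRow] = []
    for child, code in zip(children, sorted(by_food)):
        summaries = simulate_weights(
            by_food[code], group_map, n_iter=n_iter, seed=child,
            strategy=strategy, basis=basis,
        )
        summaries = {
            g: WeightSummary(
                s.mean_g, s.sd_g, s.max_g, s.q90_g, s.n_iter, seed, s.strategy
            )
            for g, s in summaries.items()
        }
        pcts = group_percentages(summaries)
        rows.extend(
            FacetWeightRow(code, g, summaries[g], pcts[g]) for g in summaries
        )
    return rows


def facet_table_to_frame(rows: Sequence[FacetWeightRow]) -> pd.DataFrame:
    """Flatten facet rows into the delimited-output schema."""
    return pd.DataFrame(
        {
            "food_code": [r.food_code for r in rows],
            "group": [r.group for r in rows],
            "mean_g": [r.summary.mean_g for r in rows],
            "sd_g": [r.summary.sd_g for r in rows],
            "max_g": [r.summary.max_g for r in rows],
            "q90_g": [r.summary.q90_g for r in rows],
            "pct": [r.pct for r in rows],
            "n_iter": [r.summary.n_iter for r in rows],
            "seed": [r.summary.seed for r in rows],
            "strategy": [r.summary.strategy for r in rows],
        }
    )
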