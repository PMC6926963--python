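"""Monte Carlo adjusted-weight estimation and group percentages."""

import math

import numpy as np
import pytest

from tfrfacet import build_facet_table, group_percentages, simulate_weights
from tfrfacet.facet_mc import Z90, facet_table_to_frame, recipe_group_weights
from conftest import make_recipe


def two_point_recipes():
    r1 = make_recipe("O010301", "a", [("rice", 1, 50, 100), ("egg", 5, 30, 40)])
    r2 = make_recipe("O010301", "b", [("rice", 1, 90, 200), ("egg", 5, 20, 30)])
    return [r1, r2]


def test_recipe_group_weights_covers_all_groups(fried_rice_recipe, group_map):
    w = recipe_group_weights(fried_rice_recipe, group_map)
    assert w == {"rice": 200, "other": 112}
    raw = recipe_group_weights(fried_rice_recipe, group_map, basis="raw")
    assert raw == {"rice": 90, "other": 127}


def test_single_recipe_is_degenerate(fried_rice_recipe, group_map):
    out = simulate_weights([fried_rice_recipe], group_map, n_iter=500, seed=3)
    s = out["rice"]
    assert (s.mean_g, s.sd_g, s.max_g, s.q90_g) == (200, 0, 200, 200)


def test_empirical_two_point_matches_closed_form(group_map):
    """Uniform draw over rice weights {100, 200}: mean 150, max 200.

    At n_iter = 10,000 the simulated mean must fall within 3 standard
    errors of 150 (SE = 50/sqrt(n_iter))."""
    out = simulate_weights(two_point_recipes(), group_map, n_iter=10_000, seed=11)
    s = out["rice"]
    assert s.max_g == 200
    assert abs(s.mean_g - 150) < 3 * 50 / math.sqrt(10_000)
    assert s.sd_g == pytest.approx(50, rel=0.05)


def test_empirical_mean_tracks_recipe_sample_mean(group_map):
    """On a lognormal corpus the simulated mean stays within 2 SE of the
    input-sample mean, and the simulated max never exceeds the largest
    per-recipe group weight (resampling cannot extrapolate)."""
    rng = np.random.default_rng(5)
    weights = rng.lognormal(np.log(150), 0.4, size=40)
    recipes = [
        make_recipe("O010302", f"r{i}", [("rice", 1, w / 2.3, w)])
        for i, w in enumerate(weights)
    ]
    out = simulate_weights(recipes, group_map, n_iter=10_000, seed=6)
    s = out["rice"]
    se = weights.std(ddof=1) / math.sqrt(10_000)
    assert abs(s.mean_g - weights.mean()) < 3 * se
    assert s.max_g <= weights.max() + 1e-12
    assert s.q90_g <= s.max_g


def test_seeded_determinism_and_seed_sensitivity(group_map):
    recipes = two_point_recipes()
    a = simulate_weights(recipes, group_map, n_iter=2_000, seed=1)
    b = simulate_weights(recipes, group_map, n_iter=2_000, seed=1)
    c = simulate_weights(recipes, group_map, n_iter=2_000, seed=2)
    assert a == b
    # distinct seeds differ, but only within Monte Carlo error
    assert a["rice"].mean_g != c["rice"].mean_g
    assert abs(a["rice"].mean_g - c["rice"].mean_g) < 5 * 50 / math.sqrt(2_000)


def test_bootstrap_mean_concentrates_on_sample_mean(group_map):
    recipes = two_point_recipes()
    out = simulate_weights(
        recipes, group_map, n_iter=5_000, seed=9, strategy="bootstrap-mean"
    )
    s = out["rice"]
    assert abs(s.mean_g - 150) < 5
    # the bootstrap-of-the-mean spread is ~sd/sqrt(n), far below the raw sd
    assert s.sd_g < 50
    assert s.max_g <= 200


def test_lognormal_strategy_moment_match(group_map):
    rng = np.random.default_rng(12)
    weights = rng.lognormal(np.log(120), 0.3, size=60)
    recipes = [
        make_recipe("O010303", f"r{i}", [("rice", 1, w, w)])
        for i, w in enumerate(weights)
    ]
    out = simulate_weights(
        recipes, group_map, n_iter=20_000, seed=13, strategy="lognormal"
    )
    s = out["rice"]
    assert s.mean_g == pytest.approx(weights.mean(), rel=0.05)
    assert s.sd_g == pytest.approx(weights.std(ddof=1), rel=0.15)


def test_simulate_weights_errors(group_map):
    with pytest.raises(ValueError, match="empty"):
        simulate_weights([], group_map, seed=1)
    recipes = two_point_recipes()
    with pytest.raises(ValueError, match="strategy"):
        simulate_weights(recipes, group_map, seed=1, strategy="jackknife")
    with pytest.raises(ValueError, match="seed"):
        simulate_weights(recipes, group_map)
    with pytest.raises(ValueError, match="n_iter"):
        simulate_weights(recipes, group_map, n_iter=0, seed=1)


@pytest.mark.parametrize(
    "means,expected",
    [
        ({"rice": 77.23, "other": 100.13}, 0.435),
        ({"rice": 176.53, "other": 92.35}, 0.657),
        ({"rice": 461.07, "other": 790.04}, 0.369),
        ({"rice": 50.0, "other": 0.0}, 1.0),
    ],
)
def test_group_percentages_from_means(means, expected):
    pct = group_percentages(means)
    assert pct["rice"] == pytest.approx(expected, abs=5e-4)
    assert sum(pct.values()) == pytest.approx(1.0, abs=1e-12)


def test_group_percentages_all_zero_rejected():
    with pytest.raises(ValueError):
        group_percentages({"rice": 0.0, "other": 0.0})


def test_q90_normal_approximation(group_map):
    """For approximately normal weights, q90 ~ mean + 1.2816 sd within 5%."""
    rng = np.random.default_rng(21)
    weights = rng.normal(300, 40, size=200).clip(min=1)
    recipes = [
        make_recipe("O010301", f"r{i}", [("rice", 1, w, w)])
        for i, w in enumerate(weights)
    ]
    s = simulate_weights(recipes, group_map, n_iter=20_000, seed=22)["rice"]
    assert s.q90_g == pytest.approx(s.mean_g + Z90 * s.sd_g, rel=0.05)


def test_build_facet_table_shape_and_determinism(group_map):
    recipes = []
    for food in ("O010301", "O010302", "O010303"):
        for i in range(4):
            recipes.append(
                make_recipe(
                    food,
                    f"{food}-{i}",
                    [("rice", 1, 100 + 10 * i, 200 + 10 * i), ("egg", 5, 50, 40)],
                )
            )
    rows = build_facet_table(recipes, group_map, n_iter=1_000, seed=33)
    assert len(rows) == 6  # 3 foods x 2 groups
    by_food = {}
    for r in rows:
        by_food.setdefault(r.food_code, 0.0)
        by_food[r.food_code] += r.pct
    assert all(total == pytest.approx(1.0, abs=1e-9) for total in by_food.values())
    # fixed seed => byte-identical serialized table
    again = build_facet_table(recipes, group_map, n_iter=1_000, seed=33)
    assert facet_table_to_frame(rows).to_csv() == facet_table_to_frame(again).to_csv()
    assert all(r.summary.seed == 33 and r.summary.n_iter == 1_000 for r in rows)
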