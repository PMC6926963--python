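import pytest
from hypothesis import settings

from tfrfacet import (
    HfdfcCode,
    Ingredient,
    Recipe,
    default_group_map,
    default_lexicon,
    descriptor_from_sub_code,
)
from tfrfacet import io

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def make_recipe(food_code, recipe_id, parts):
    """parts: iterable of (name, sub_code, raw_g, cooked_g)."""
    return Recipe(
        HfdfcCode(food_code),
        recipe_id,
        tuple(
            Ingredient(name, descriptor_from_sub_code(sub), raw, cooked)
            for name, sub, raw, cooked in parts
        ),
    )


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def group_map():
    return default_group_map()


@pytest.fixture
def fried_rice_recipe():
    return make_recipe(
        "O010301",
        "r1",
        [
            ("rice", 1, 90, 200),
            ("egg", 5, 55, 50),
            ("pork", 6, 40, 35),
            ("cabbage", 8, 30, 25),
            ("salt", 14, 2, 2),
        ],
    )


@pytest.fixture(scope="session")
def study_facet_rows():
    """Facet rows built from the packaged adjusted-weight means."""
    return io.read_facet_table(io.packaged_path("facet_means.csv"))


@pytest.fixture(scope="session")
def study_consumption():
    return io.read_consumption(io.packaged_path("consumption.csv"))


@pytest.fixture(scope="session")
def study_strata():
    return io.read_population(io.packaged_path("population.yaml"))


@pytest.fixture(scope="session")
def cadmium():
    return io.read_contaminant(io.packaged_path("contaminant.yaml"))
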