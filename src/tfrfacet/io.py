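"""File readers/writers and run configuration.

All tabular formats are comma-separated UTF-8 text with a required header
row (ingredient names may be Chinese).  Every validation error names the
offending file, row, or key; nothing is silently coerced.

Schemas
-------
recipes file
    ``food_code, recipe_id, ingredient, raw_g, cooked_g[, descriptor[, source]]``
    — when the optional ``descriptor`` column carries a sub-code it
    overrides the lexicon for that row.
lexicon file
    ``name, sub_code``
consumption file
    ``food_code, stratum, cr_g_per_day``
population config (YAML)
    ``strata: {label: body_weight_kg}``
contaminant config (YAML)
    ``name, concentration_mg_per_kg`` (scalar or ``{group: value}`` mapping),
    ``rfd_mg_per_kg_day``, optional ``provenance``
facet table
    the columns written by :func:`tfrfacet.facet_mc.facet_table_to_frame`;
    on read only ``food_code, group, mean_g`` are required — percentages are
    recomputed from the means when absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .codes import CodeError, HfdfcCode, descriptor_from_sub_code
from .exposure import Contaminant, ConsumptionRecord, Stratum
from .facet_mc import FacetWeightRow, WeightSummary, group_percentages
from .recipes import Ingredient, Lexicon, Recipe, classify_ingredient

__all__ = [
    "SchemaError",
    "RunConfig",
    "packaged_path",
    "read_recipes",
    "write_recipes",
    "read_lexicon",
    "read_consumption",
    "write_consumption",
    "read_population",
    "read_contaminant",
    "read_facet_table",
    "write_facet_table",
]


class SchemaError(ValueError):
    """A file that does not match its declared schema."""


def packaged_path(name: str) -> Path:
    """Path to a data file shipped with the package."""
    return Path(str(files("tfrfacet.data").joinpath(name)))


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_recipes(
    path,
    lexicon: Lexicon | None = None,
    *,
    strict: bool = True,
    fallback_sub_code: int = 14,
) -> list[Recipe]:
    """Read and validate a recipes file.

    Rows sharing (food_code, recipe_id) form one recipe.  Descriptors come
    from the ``descriptor`` column where present, otherwise from the
    lexicon; in lenient mode (``strict=False``) unknown ingredient names
    fall back to ``fallback_sub_code``.  Error messages carry 1-based file
    row numbers (header = row 1).
    """
    df = pd.read_csv(path)
    _require_columns(
        df, ["food_code", "recipe_id", "ingredient", "raw_g", "cooked_g"], path
    )
    has_descriptor = "descriptor" in df.columns
    has_source = "source" in df.columns
    fallback = descriptor_from_sub_code(fallback_sub_code) if not strict else None

    grouped: dict[tuple[str, str], list[Ingredient]] = {}
    sources: dict[tuple[str, str], str] = {}
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header occupies row 1
        try:
            code = HfdfcCode(str(row["food_code"]).strip())
        except CodeError as exc:
            raise SchemaError(f"{path}, row {rownum}: {exc}") from exc
        for col in ("raw_g", "cooked_g"):
            w = row[col]
            if not (isinstance(w, (int, float)) and math.isfinite(w)) or w < 0:
                raise SchemaError(
                    f"{path}, row {rownum}: {col}={w!r} must be a finite "
                    "non-negative number"
                )
        if has_descriptor and not pd.isna(row["descriptor"]):
            try:
                desc = descriptor_from_sub_code(int(row["descriptor"]))
            except (CodeError, ValueError) as exc:
                raise SchemaError(f"{path}, row {rownum}: {exc}") from exc
        else:
            if lexicon is None:
                raise SchemaError(
                    f"{path}, row {rownum}: no descriptor column value and "
                    "no lexicon supplied"
                )
            try:
                desc = classify_ingredient(
                    str(row["ingredient"]), lexicon, fallback=fallback
                )
            except KeyError as exc:
                raise SchemaError(f"{path}, row {rownum}: {exc}") from exc
        key = (str(row["food_code"]).strip(), str(row["recipe_id"]))
        grouped.setdefault(key, []).append(
            Ingredient(
                str(row["ingredient"]),
                desc,
                float(row["raw_g"]),
                float(row["cooked_g"]),
            )
        )
        if has_source and not pd.isna(row["source"]):
            sources[key] = str(row["source"])

    recipes = []
    for (code_text, recipe_id), ingredients in grouped.items():
        try:
            recipes.append(
                Recipe(
                    HfdfcCode(code_text),
                    recipe_id,
                    tuple(ingredients),
                    sources.get((code_text, recipe_id), ""),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}, recipe {recipe_id!r}: {exc}") from exc
    return recipes


def write_recipes(recipes: Sequence[Recipe], path) -> None:
    rows = [
        {
            "food_code": r.food_code.text,
            "recipe_id": r.recipe_id,
            "ingredient": i.name,
            "raw_g": i.raw_weight_g,
            "cooked_g": i.cooked_weight_g,
            "descriptor": i.descriptor.sub_code,
            "source": r.source,
        }
        for r in recipes
        for i in r.ingredients
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_lexicon(path) -> Lexicon:
    df = pd.read_csv(path)
    _require_columns(df, ["name", "sub_code"], path)
    try:
        return Lexicon.from_pairs(zip(df["name"], df["sub_code"]))
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def read_consumption(path) -> list[ConsumptionRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["food_code", "stratum", "cr_g_per_day"], path)
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                ConsumptionRecord(
                    str(row["stratum"]),
                    HfdfcCode(str(row["food_code"]).strip()).text,
                    float(row["cr_g_per_day"]),
                )
            )
        except (CodeError, ValueError) as exc:
            raise SchemaError(f"{path}, row {int(idx) + 2}: {exc}") from exc
    return records


def write_consumption(records: Sequence[ConsumptionRecord], path) -> None:
    pd.DataFrame(
        {
            "food_code": [r.food_code for r in records],
            "stratum": [r.stratum for r in records],
            "cr_g_per_day": [r.cr_g_per_day for r in records],
        }
    ).to_csv(path, index=False)


def read_population(path) -> list[Stratum]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "strata" not in doc:
        raise SchemaError(f"{path}: expected a mapping with a 'strata' key")
    strata = []
    for label, bw in doc["strata"].items():
        try:
            strata.append(Stratum(str(label), float(bw)))
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}, stratum {label!r}: {exc}") from exc
    return strata


def read_contaminant(path) -> Contaminant:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: expected a mapping")
    for key in ("name", "concentration_mg_per_kg", "rfd_mg_per_kg_day"):
        if key not in doc:
            raise SchemaError(f"{path}: missing key {key!r}")
    conc = doc["concentration_mg_per_kg"]
    by_group = None
    if isinstance(conc, dict):
        by_group = {str(k): float(v) for k, v in conc.items()}
        scalar = max(by_group.values(), default=0.0)
    else:
        scalar = float(conc)
    try:
        return Contaminant(
            str(doc["name"]),
            scalar,
            float(doc["rfd_mg_per_kg_day"]),
            str(doc.get("provenance", "")),
            by_group,
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def read_facet_table(path) -> list[FacetWeightRow]:
    """Read a facet weight table; recompute percentages from the means."""
    df = pd.read_csv(path)
    _require_columns(df, ["food_code", "group", "mean_g"], path)
    rows: list[FacetWeightRow] = []
    for code, sub in df.groupby("food_code", sort=False):
        means = dict(zip(sub["group"], sub["mean_g"].astype(float)))
        try:
            pcts = group_percentages(means)
        except ValueError as exc:
            raise SchemaError(f"{path}, food {code!r}: {exc}") from exc
        for _, row in sub.iterrows():
            summary = WeightSummary(
                mean_g=float(row["mean_g"]),
                sd_g=float(row.get("sd_g", 0.0) or 0.0),
                max_g=float(row["max_g"]) if "max_g" in sub else float("inf"),
                q90_g=float(row.get("q90_g", 0.0) or 0.0),
                n_iter=int(row["n_iter"]) if "n_iter" in sub else 0,
                seed=int(row["seed"]) if "seed" in sub and not pd.isna(row["seed"]) else None,
                strategy=str(row["strategy"]) if "strategy" in sub else "external",
            )
            rows.append(
                FacetWeightRow(
                    str(code), str(row["group"]), summary, pcts[str(row["group"])]
                )
            )
    return rows


def write_facet_table(rows: Sequence[FacetWeightRow], path) -> None:
    from .facet_mc import facet_table_to_frame

    facet_table_to_frame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run.

    Paths default to the packaged study fixtures so the assessment runs
    end-to-end offline; CLI flags override any field.
    """

    recipes_path: Path | None = None
    lexicon_path: Path = field(default_factory=lambda: packaged_path("lexicon.csv"))
    facet_path: Path = field(default_factory=lambda: packaged_path("facet_means.csv"))
    consumption_path: Path = field(
        default_factory=lambda: packaged_path("consumption.csv")
    )
    population_path: Path = field(
        default_factory=lambda: packaged_path("population.yaml")
    )
    contaminant_path: Path = field(
        default_factory=lambda: packaged_path("contaminant.yaml")
    )
    n_iter: int = 10_000
    seed: int | None = None
    strategy: str = "empirical"
    weight_basis: str = "cooked"
    rounding: str = "standard"

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.weight_basis not in ("cooked", "raw"):
            raise ValueError(f"unknown weight basis {self.weight_basis!r}")
        if self.rounding not in ("standard", "legacy"):
            raise ValueError(f"unknown rounding mode {self.rounding!r}")
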