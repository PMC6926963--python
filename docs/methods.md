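# Methods

## Model and pipeline

The package treats a composite food as a mixture of ingredient groups whose
composition is estimated from a corpus of recipes, and screens a single
contaminant against a chronic oral reference dose:

1. Each recipe is aggregated to per-descriptor cooked (or raw) weights;
   descriptors are partitioned into reporting groups (default:
   `rice` = whole grains vs `other` = the remaining thirteen descriptors —
   water and seasonings included, since nothing in the data model excludes
   them from recipe totals).
2. Per food, group weights are summarized by Monte Carlo resampling
   (below); the group percentage is the ratio of group means,
   `pct(g) = mean_g / Σ mean_g'`, **not** the mean of per-recipe ratios.
   The two differ for skewed weights; the ratio-of-means convention is the
   one consistent with decomposing a population-level consumption rate.
3. Consumption decomposes linearly, `CR_group = CR_food × pct`, and dose
   and hazard follow `ADD = C × (CR_group/1000)/BW` and `HI = ADD/RfD`.
   The `/1000` converts g food/day to kg food/day; dose equations are
   often written without it, but it is required for the conventional units
   (C in mg/kg, ADD in mg/kg-bw/day) to resolve, and it is part of the
   implemented formula (`tfrfacet.exposure.ADD_FORMULA`).

Assumptions: composition percentages estimated from recipes transfer to
the consumed foods; a single concentration applies to the whole food mass
unless a per-group mapping is configured; strata are opaque labels — the
"mean" stratum is an independent input (population-level CR and BW), never
derived from the male/female rows.

## Monte Carlo strategies

`simulate_weights` runs `n_iter` iterations (default 10,000) with an
explicit seed (never a hidden global default; the seed is recorded in every
output row). Three strategies:

- **empirical** (default): each iteration draws one recipe uniformly with
  replacement and records its per-group weight. The simulated distribution
  is the empirical recipe distribution: the mean converges to the recipe
  sample mean, and the max can reach (but never exceed) the largest
  per-recipe group weight. This default was chosen because published
  adjusted-weight tables of this kind show Max values several times the
  mean, which a bootstrap-of-the-mean cannot produce.
- **bootstrap-mean**: each iteration is the mean of a resample of size
  `n_recipes` — the sampling distribution of the mean, with spread
  ~ SD/√n.
- **lognormal**: a moment-matched lognormal per group
  (σ² = ln(1 + CV²), μ = ln(mean) − σ²/2); groups absent from every
  recipe stay identically zero.

The summary reports mean, sample SD, max and the 90th percentile of the
simulated draws (linear interpolation). Under approximate normality
q90 ≈ mean + 1.2816·SD; the test suite asserts this within 5% on synthetic
normal corpora. A per-iteration "total" (sum of group draws) can be
requested; note that when summaries are produced by independent per-group
simulations, the sum of group means and a jointly simulated total need not
agree exactly.

## Rounding conventions

Internal computation is never rounded. The report layer rounds half-up:
CR to 2 decimals, ADD to 6, HI to 2 — the convention that reproduces
published tables of this kind. Composite (whole-food) HI is reported from
the unrounded group sum by default; `rounding="legacy"` instead sums the
*rounded* group HIs, matching summary tables that were assembled from
already-rounded components.

Reproduction caveats established while validating against the packaged
study fixtures (and asserted by the acceptance tests):

- All 18 decomposed-CR cells reproduce from the printed (2-decimal)
  percentages; all 18 ADD cells reproduce only when the *unrounded*
  percentages flow through the pipeline — with rounded percentages one
  cell (sushi, mean stratum, other group) lands on the opposite side of
  the 6th decimal.
- 13 of the 18 group HI cells in the reference table are arithmetically
  consistent with their own inputs; the other 5 (fried rice mean/rice,
  fried rice female/rice, sushi mean/rice, rice ball mean/rice, rice ball
  male/other) are not reproducible under any rounding convention and are
  documented rather than asserted.
- The fried-rice rice share computed from the printed group means is
  65.654%, which rounds to 65.7% rather than the printed 65.6% — a
  rounding-boundary artifact of the printed means. The corresponding test
  is expected to fail and says so in its docstring; sushi (43.5%) and rice
  ball (36.9%) reproduce exactly.

## Synthetic data

The generator emulates a recipe corpus for rice-based composite foods:
per-food group weights drawn lognormal (weights are positive and
right-skewed; a zero-truncated normal family is available), split across
the group's descriptors by a Dirichlet draw, with ingredient names sampled
from the packaged lexicon so generated files pass strict classification
unchanged. The default study conditions (`rice_study_spec`) use three
foods with 6/31/79 recipes, group means/SDs matched to the packaged
adjusted-weight table, point-mass per-capita consumption rates, and a
cooked/raw yield of 2.3 (typical for boiled rice; applied uniformly, a
deliberate simplification — real yields vary by ingredient).

What the generator does **not** emulate: survey sampling weights and
demographics, recipe deduplication, ingredient-level concentration
heterogeneity, cooking losses of contaminant mass. Passing recovery tests
therefore show the estimator is correct under the stated mixture model,
not that real recipe scrapes are unbiased samples of what people cook.

Ground truth (true means and analytic percentages) is always emitted
alongside generated data; tests compare against it directly.

## Numerical and design choices

- Percentages are exact ratios of means; fractions per food sum to 1 to
  1e-9 or better by construction.
- Composite dose additivity is exact (before rounding) because the
  percentages partition unity.
- Degenerate inputs: a single recipe yields a point-mass summary
  (SD = 0, max = q90 = mean); zero-weight groups yield zero summaries and
  a zero percentage; an all-zero food is an error (percentages undefined).
- Classification is exact-match on case-folded, whitespace-collapsed
  names. No fuzzy matching: misses surface as errors (strict mode) or a
  configurable fallback descriptor (lenient mode, for noisy scrapes).
- Hierarchy level of a classification code is derived as
  1 + digit-pairs and is informational only; no computation uses it.
- Legacy description facets F01–F06 parse as opaque tokens so older code
  strings round-trip; only F07 carries recipe semantics.
- Problem sizes in the test and acceptance runs (corpora up to 10 foods ×
  100 recipes, 10,000 iterations; 1,000 random assessment tuples) were
  chosen as the smallest sizes at which the statistical checks are
  well-powered.

## Known limitations

Point-estimate screening only: no distributional exposure, no carcinogenic
slope-factor route, a single adult age band, no bioaccessibility or
cooking-loss correction. Whether intermediate classification codes (e.g. a
4-digit prefix of a 6-digit code) are valid standalone identifiers is left
to the caller; the parser accepts any even digit count from 2 to 8.
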