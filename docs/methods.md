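# Methods

## Scope and data model

`foodprofiler` operates on packaged food and beverage records: a product id,
market category/sub-category labels, a launch year, an ordered free-text
ingredient list, and a nutrient panel declared per 100 g (solids) or 100 ml
(beverages). Eleven nutrients are modeled — energy (kcal), total fat,
saturated fat, total sugars, added sugars (g), sodium (mg), protein, fiber
(g), calcium, iron (mg) and riboflavin (mg). Every value is optional, and a
missing value is distinct from a declared zero; panel invariants
(saturated fat ≤ total fat, added sugars ≤ total sugars, non-negativity) are
enforced at construction. Fiber carries a provenance flag separating declared
from imputed values; to keep that flag CSV-round-trippable the product CSV
layout includes a `fiber_declared` column alongside the documented nutrient
columns.

## Sample curation

Curation applies three filters in a fixed order, each counted against the set
entering that stage: (1) products whose panel declares no nutrient at all;
(2) exact duplicates — identical nutrition (missing compares equal to
missing, values exactly equal) and identical normalized (trimmed, case-folded)
ingredient sequences, with packaging ignored and the first occurrence in
input order kept; (3) excluded market categories (non-food, alcoholic,
supplementary products; config-supplied, case-insensitive). "No nutrient
information" is read as a fully blank panel: partially missing panels survive
curation and surface later as per-system "not classifiable" outcomes, which
matches how the downstream engines treat insufficient data. The report's
arithmetic identity (output = input − stage removals) is enforced by the
`CurationReport` type itself. Curation is idempotent, and the stage order is
part of the contract.

## Profiling engines

All three nutrient-profiling engines are pure functions of
(product, ruleset), where the ruleset is a validated YAML configuration:
ordered category-match patterns over (category, sub-category, beverage flag)
with first-match precedence, per-category criteria, and per-category required
nutrients. A product is NOT_CLASSIFIABLE when no category matches, when a
required nutrient is missing, or when the declared basis contradicts the
product type (beverage panels must be per 100 ml, solids per 100 g; no
density conversion is attempted).

* **DOH-style scoring.** Each score rule holds ascending (upper bound,
  points) bands plus `above_points` for values beyond the last bound;
  descending profiles score limit nutrients, ascending profiles score
  nutrients to encourage (fiber, protein). The overall score is
  100 × Σ awarded / Σ maximum; Group A at ≥ 80%, Group B at 60–<80%,
  Group C below (cutpoints configurable, boundaries inclusive as stated).
  Auto-prohibited categories (e.g. carbonated soft drinks, confectionery)
  return AUTO_PROHIBITED before any scoring. Marketing criteria are a
  separate conjunction evaluated independently of the group label, because a
  Group A product can still fail the marketing layer; the healthy/unhealthy
  dichotomy uses the group label only.
* **WHO SEA-style thresholds.** Fail-any: one exceedance prohibits marketing.
  "Must not exceed" is a strict `>` — a value exactly at the threshold
  passes. Violated nutrients are reported for auditability.
* **HCL-style eligibility.** Eligible iff every criterion holds; criteria may
  point either way (≤ limits, ≥ encouragements).

The official Thai and WHO threshold documents are not public as
machine-readable tables; the shipped rulesets are synthetic fixtures whose
structure (not values) mirrors those systems. Every comparator and band is
config, so official tables can be dropped in without code changes.

## NOVA classification

Ingredient text is tokenized by splitting on `;` and `,` outside
parentheses; parenthesized sub-ingredients are parsed recursively and
flattened after their parent; tokens are case-folded, trimmed, and stripped
of percentage annotations. Unbalanced parentheses warn and parse best-effort.

The cascade is fixed: NOT_CLASSIFIABLE when no ingredient list is provided;
UPF when any token matches a marker (substances of no culinary use, cosmetic
additive classes, or an E-number pattern `E` + 3–4 digits minus a config
allowlist); PCI when the product sits in a culinary-ingredient category
(oils/fats) *and* every token is a culinary substance — the category gate
prevents "sugar" inside a biscuit list from triggering PCI; P when any token
is a culinary substance or a preservation/addition term (salt, sugar, oil,
brine, canned, smoked, ...); MP otherwise. Marker presence dominates all
other evidence.

Matching is deliberately literal and fuzzy-free: term equality, word-boundary
occurrence, or — for multi-word terms — the term's words in order within the
token's words (so "modified starch" matches "modified corn starch").
A per-product override table can represent manual adjudications, since
published NOVA assignments involve human review that no lexicon reproduces.

## Fiber estimation

For products without declared fiber, rules apply in strict precedence:
(1) sub-categories that typically contain no fiber → 0; (2) no fiber-bearing
ingredient (industrial fibers such as inulin, polydextrose, oligofructose
count) → 0; (3) similar-type sub-categories (sweet biscuits, wet soups, ...)
→ arithmetic mean of that sub-category's declared non-zero values;
(4) otherwise the most similar declared-fiber product in the same
sub-category, with similarity = Jaccard overlap of ingredient tokens, a
configurable floor (default 0.5) and earliest-donor tie-breaking; (5) else a
conservative 1 g/100 g. The similar-product rule is a deterministic stand-in
for what is, in published practice, a manual matching step. Declared values
are never overwritten; because every learned statistic (means, donor pools)
is computed from declared values only, a second pass reproduces the first
exactly. The imputer follows the scikit-learn fit/transform contract: `fit`
learns sub-category means and donors, `transform` applies the cascade and
records a rule-count report that partitions the input.

## Agreement analysis

Per-system outcomes collapse to healthy (Group A, marketing permitted, logo
eligible, non-UPF — MP, PCI and P combined) versus unhealthy;
not-classifiable propagates, and all statistics run on the complete-case
subset (products classifiable by all four systems). Cohen's kappa uses the
marginal-product expected agreement; the degenerate pe = 1 case (constant
marginals with perfect agreement) returns κ = 1 with a degeneracy note
rather than failing, as it is only reachable on constant inputs. Reported
kappas are rounded half-up to 3 decimals; interpretation bands are applied
to the kappa rounded to 2 decimals first (so 0.431 is "moderate" and 0.094
"none to slight"), with band edges inclusive. Complementary outputs are the
systems-met distribution (how many of the four systems call each product
healthy, 0–4), and the UPF share among each profiling system's healthy
products.

The packaged published 2×2 count tables are internally consistent with the
published kappas at 3 decimals for five of the six system pairs; the sixth
(HCL–NOVA) recomputes to 0.095 against a printed 0.094, and the three
NOVA-pair percent agreements recompute ≈0.03 points above their printed
values (e.g. 79.82 vs 79.79). The package reports count-derived values and
does not adjust them toward the printed figures; tests pin the count-derived
numbers for those cells with a 0.05-point tolerance and printed values
elsewhere.

## Synthetic data generator

The generator emulates a raw market-launch feed rather than a curated
analysis set. Defaults are fixed at the emulated feed's documented rates
where such rates exist: 45.7% of records carry no nutrient panel, 3% are
verbatim duplicates, 2% omit the ingredient list, 60% leave fiber
undeclared, and per-category ultra-processing-marker rates sit near
realistic ultra-processed shares (0.62–0.95 across categories, 0.10 for
oils/fats). Category mix, sub-category taxonomy and per-category nutrient
log-normal (median, log-sigma) parameters are generator choices set once to
typical per-100 g/ml magnitudes; saturated fat and added sugars are drawn as
fractions of their aggregates so panel invariants hold by construction.
Nutrient values are rounded to 2 decimals to keep draws platform-stable.
Each product consumes its own counter-derived substream
(`default_rng([seed, index])`), so generation is deterministic and
insertion-stable: growing n never changes earlier products.

The labeled benchmark generator builds products whose intended outcomes are
attainable by construction: healthy-intent products place every limited
nutrient 10% inside the *tightest* applicable bound across all three
profiling systems (including the DOH top band and marketing criteria) and
every encouraged nutrient 10% above its highest floor; unhealthy-intent
products sit 25% outside every bound, which forces zero points on all DOH
score rules (Group C), at least one WHO SEA exceedance, and an HCL failure.
Contradictory constraints raise a generation error naming the product.
Intended truth is stored as the per-system dichotomy
(healthy/unhealthy/not-classifiable), which gives well-defined labels for
auto-prohibited DOH categories and for categories a system does not cover
(the fixture HCL omits confectionery by design). Benchmark products always
declare required nutrients and ingredients: the benchmark probes label
recovery, not missing-data handling. Because recovery is checked with the
same configurations that generated the products, a perfect score certifies
the engines' fidelity to their configuration — it says nothing about how
well the fixture thresholds approximate any official system or how either
would behave on real market data, where nutrient distributions, ingredient
vocabulary and category mixes are far messier.

## Problem sizes and numerical conventions

The test suite exercises the property checks at the sizes that make them
meaningful while staying fast: 1,000 random 2×2 tables against a
direct-definition kappa oracle (plus scikit-learn's implementation as an
independent cross-check), 1,000 random products for threshold monotonicity,
1,000 synthetic ingredient lists for marker dominance and cascade order, a
5,000-product set for imputation idempotence, and a 2,000-product benchmark
for label recovery. Floating-point ties at DOH cutpoints and WHO SEA
thresholds are resolved by the documented inclusive/strict conventions, not
by tolerances; all reporting rounds half-up (never banker's rounding) at the
stated precision.

## Known limitations

Fixture rulesets and the lexicon are illustrative; agreement statistics on
synthetic data do not estimate real-market agreement. Ingredient matching is
literal (no spelling variants beyond the listed terms, no translation).
Serving-size arithmetic, density conversion between g and ml bases, and
nutrient imputation beyond fiber are out of scope.
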