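"""Seeded generation of Mintel-like packaged-food product sets.

Two generators share one :class:`GeneratorSpec`:

* :func:`generate_products` emulates a raw market-launch data feed —
  per-category log-normal nutrient panels with controlled missingness,
  ingredient lists assembled from the packaged lexicon at configurable
  ultra-processing-marker rates, plus injected verbatim duplicates and
  fully blank panels, so the curation pipeline has something to remove.
* :func:`generate_labeled_benchmark` builds complete-data products whose
  intended outcome under every fixture ruleset is attainable by
  construction: "healthy" products sit 10% inside every relevant
  threshold (and in the top band of every score rule), "unhealthy"
  products sit 25% outside, and ingredient lists are composed to force
  the intended NOVA group.  The returned truth table maps product ids to
  the intended per-system dichotomy and NOVA class.

Determinism: each product draws from its own counter-derived substream
(``default_rng([seed, index])``), so inserting or dropping products never
shifts later draws.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .nova import IngredientLexicon, NovaClass, default_lexicon
from .products import Basis, NutrientPanel, Product, ProductSet
from .profiling import (
    Comparator,
    RuleSet,
    ScoreRule,
    System,
    assign_system_category,
    default_ruleset,
)

__all__ = [
    "GeneratorSpec",
    "LabeledBenchmark",
    "GenerationError",
    "generate_products",
    "generate_labeled_benchmark",
]

DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "Beverages": 0.24,
    "Snacks": 0.23,
    "Bakery": 0.17,
    "Dairy": 0.08,
    "Ready Meals": 0.10,
    "Sauces & Seasonings": 0.06,
    "Confectionery": 0.09,
    "Fats & Oils": 0.03,
}

DEFAULT_SUBCATEGORIES: dict[str, tuple[str, ...]] = {
    "Beverages": ("Carbonated Soft Drinks", "Juice Drinks", "Herbal Drinks"),
    "Snacks": ("Potato Snacks", "Nuts", "Rice Snacks"),
    "Bakery": ("Sweet Biscuits", "Bread", "Cakes"),
    "Dairy": ("Drinking Yogurt", "Cheese"),
    "Ready Meals": ("Wet Soups", "Instant Noodles"),
    "Sauces & Seasonings": ("Table Sauces", "Dressings"),
    "Confectionery": ("Chocolate", "Gum Jellies"),
    "Fats & Oils": ("Cooking Oils", "Margarine"),
}

# (median, log-scale sigma) of a log-normal draw, per 100 g (ml beverages).
DEFAULT_NUTRIENT_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "Beverages": {
        "energy": (35, 0.6), "total_fat": (0.5, 0.8), "total_sugars": (8, 0.6),
        "sodium": (30, 0.8), "protein": (0.8, 0.8), "fiber": (0.3, 0.9),
        "calcium": (40, 0.7), "iron": (0.3, 0.8), "riboflavin": (0.05, 0.8),
    },
    "Snacks": {
        "energy": (480, 0.2), "total_fat": (22, 0.4), "total_sugars": (6, 0.8),
        "sodium": (550, 0.6), "protein": (7, 0.5), "fiber": (3, 0.6),
        "calcium": (30, 0.8), "iron": (1.2, 0.7), "riboflavin": (0.1, 0.8),
    },
    "Bakery": {
        "energy": (430, 0.2), "total_fat": (18, 0.4), "total_sugars": (22, 0.5),
        "sodium": (300, 0.5), "protein": (6, 0.4), "fiber": (2, 0.6),
        "calcium": (40, 0.8), "iron": (1.5, 0.7), "riboflavin": (0.1, 0.8),
    },
    "Dairy": {
        "energy": (90, 0.4), "total_fat": (3.5, 0.6), "total_sugars": (10, 0.5),
        "sodium": (60, 0.6), "protein": (3.2, 0.4), "fiber": (0.2, 1.0),
        "calcium": (110, 0.4), "iron": (0.2, 0.8), "riboflavin": (0.2, 0.6),
    },
    "Ready Meals": {
        "energy": (120, 0.5), "total_fat": (5, 0.6), "total_sugars": (3, 0.8),
        "sodium": (400, 0.6), "protein": (6, 0.5), "fiber": (1.5, 0.7),
        "calcium": (30, 0.8), "iron": (1.0, 0.7), "riboflavin": (0.1, 0.8),
    },
    "Sauces & Seasonings": {
        "energy": (150, 0.6), "total_fat": (8, 0.9), "total_sugars": (12, 0.7),
        "sodium": (900, 0.7), "protein": (2, 0.7), "fiber": (1, 0.8),
        "calcium": (25, 0.8), "iron": (0.8, 0.8), "riboflavin": (0.05, 0.9),
    },
    "Confectionery": {
        "energy": (450, 0.2), "total_fat": (15, 0.6), "total_sugars": (55, 0.3),
        "sodium": (80, 0.8), "protein": (4, 0.6), "fiber": (1.5, 0.8),
        "calcium": (50, 0.8), "iron": (1.0, 0.8), "riboflavin": (0.1, 0.8),
    },
    "Fats & Oils": {
        "energy": (800, 0.1), "total_fat": (90, 0.1), "total_sugars": (0.5, 1.0),
        "sodium": (30, 1.0), "protein": (0.2, 1.0), "fiber": (0.05, 1.0),
        "calcium": (5, 1.0), "iron": (0.1, 1.0), "riboflavin": (0.01, 1.0),
    },
}

DEFAULT_MISSING_RATES: dict[str, float] = {
    "energy": 0.03, "total_fat": 0.05, "saturated_fat": 0.15,
    "total_sugars": 0.05, "added_sugars": 0.50, "sodium": 0.08,
    "protein": 0.15, "calcium": 0.70, "iron": 0.75, "riboflavin": 0.85,
}

# probability an ingredient list receives >= 1 ultra-processing marker
DEFAULT_UPF_MARKER_RATES: dict[str, float] = {
    "Beverages": 0.78, "Snacks": 0.77, "Bakery": 0.88, "Dairy": 0.80,
    "Ready Meals": 0.90, "Sauces & Seasonings": 0.62, "Confectionery": 0.95,
    "Fats & Oils": 0.10,
}


class GenerationError(RuntimeError):
    """Raised when an intended benchmark label is unattainable."""


class GeneratorSpec(BaseModel):
    """Parameters of the synthetic product generator.

    Default rates mirror the market feed the generator emulates: ~46% of
    raw records carry no nutrient panel, ~3% are verbatim duplicates, ~2%
    omit the ingredient list, and roughly 60% of products leave fiber
    undeclared.  Per-category marker rates track realistic ultra-processed
    shares of each category.
    """

    model_config = ConfigDict(frozen=True)

    n_products: int = Field(ge=0)
    seed: int = Field(ge=0)
    category_mix: dict[str, float] = DEFAULT_CATEGORY_MIX
    subcategories: dict[str, tuple[str, ...]] = DEFAULT_SUBCATEGORIES
    nutrient_distributions: dict[str, dict[str, tuple[float, float]]] = (
        DEFAULT_NUTRIENT_DISTRIBUTIONS
    )
    missing_rates: dict[str, float] = DEFAULT_MISSING_RATES
    fiber_undeclared_rate: float = Field(default=0.60, ge=0, le=1)
    upf_marker_rate: dict[str, float] = DEFAULT_UPF_MARKER_RATES
    pci_rate: float = Field(default=0.60, ge=0, le=1)
    processed_rate: float = Field(default=0.45, ge=0, le=1)
    duplicate_rate: float = Field(default=0.03, ge=0, le=1)
    no_nutrient_rate: float = Field(default=0.457, ge=0, le=1)
    no_ingredient_rate: float = Field(default=0.02, ge=0, le=1)
    healthy_rate: float = Field(default=0.25, ge=0, le=1)

    @model_validator(mode="after")
    def _validate(self) -> "GeneratorSpec":
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix sums to {total}, expected 1")
        for cat, p in self.category_mix.items():
            if not 0 <= p <= 1:
                raise ValueError(f"category_mix[{cat!r}] outside [0, 1]")
            if cat not in self.subcategories:
                raise ValueError(f"no subcategories for category {cat!r}")
        for cat, p in self.upf_marker_rate.items():
            if not 0 <= p <= 1:
                raise ValueError(f"upf_marker_rate[{cat!r}] outside [0, 1]")
        for nut, p in self.missing_rates.items():
            if not 0 <= p <= 1:
                raise ValueError(f"missing_rates[{nut!r}] outside [0, 1]")
        return self


class LabeledBenchmark(BaseModel):
    """Products plus the ground truth they were constructed to satisfy.

    ``truth[product_id]`` holds the intended NOVA class and the intended
    healthy/unhealthy/not-classifiable dichotomy under each fixture
    ruleset.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True, frozen=True)

    products: ProductSet
    truth: dict[str, dict[str, str]]

    @model_validator(mode="after")
    def _covered(self) -> "LabeledBenchmark":
        missing = [p.product_id for p in self.products if p.product_id not in self.truth]
        if missing:
            raise ValueError(f"products missing from truth table: {missing[:5]}")
        return self


def _rng_for(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def _choice(rng: np.random.Generator, mix: dict[str, float]) -> str:
    cats = sorted(mix)
    probs = np.array([mix[c] for c in cats], dtype=float)
    return cats[rng.choice(len(cats), p=probs / probs.sum())]


def _draw_panel(rng: np.random.Generator, spec: GeneratorSpec, category: str) -> NutrientPanel:
    dists = spec.nutrient_distributions[category]
    values: dict[str, Optional[float]] = {}
    for nutrient, (median, sigma) in dists.items():
        if rng.random() < spec.missing_rates.get(nutrient, 0.0):
            values[nutrient] = None
        else:
            values[nutrient] = float(np.round(median * np.exp(sigma * rng.standard_normal()), 2))
    # dependent nutrients as fractions, preserving the panel invariants
    fat = values.get("total_fat")
    if fat is not None and rng.random() >= spec.missing_rates.get("saturated_fat", 0.0):
        values["saturated_fat"] = float(np.round(fat * rng.uniform(0.2, 0.6), 2))
    sugars = values.get("total_sugars")
    if sugars is not None and rng.random() >= spec.missing_rates.get("added_sugars", 0.0):
        values["added_sugars"] = float(np.round(sugars * rng.uniform(0.3, 0.9), 2))
    fiber = values.pop("fiber", None)
    declared = fiber is not None and rng.random() >= spec.fiber_undeclared_rate
    basis = Basis.PER_100_ML if category == "Beverages" else Basis.PER_100_G
    return NutrientPanel(
        basis=basis,
        fiber=fiber if declared else None,
        fiber_declared=declared,
        **{k: v for k, v in values.items() if k != "fiber"},
    )


def _sample_terms(rng: np.random.Generator, terms: tuple[str, ...], k: int) -> list[str]:
    k = min(k, len(terms))
    idx = rng.choice(len(terms), size=k, replace=False)
    return [terms[int(i)] for i in idx]


def _build_ingredients(
    rng: np.random.Generator,
    spec: GeneratorSpec,
    lexicon: IngredientLexicon,
    category: str,
) -> tuple[list[str], NovaClass]:
    """Assemble an ingredient list and its intended NOVA class."""
    if rng.random() < spec.no_ingredient_rate:
        return [], NovaClass.NOT_CLASSIFIABLE
    u = rng.random()
    pci_like = category == "Fats & Oils"
    if u < spec.upf_marker_rate.get(category, 0.5):
        intent = NovaClass.UPF
    elif pci_like and rng.random() < spec.pci_rate:
        intent = NovaClass.PCI
    elif rng.random() < spec.processed_rate:
        intent = NovaClass.P
    else:
        intent = NovaClass.MP
    base = _sample_terms(rng, lexicon.whole_foods, int(rng.integers(2, 6)))
    if intent is NovaClass.MP:
        return base, intent
    if intent is NovaClass.PCI:
        return _sample_terms(rng, lexicon.pci_substances, int(rng.integers(1, 3))), intent
    added = _sample_terms(rng, lexicon.preservation_or_added_terms, 1)
    if intent is NovaClass.P:
        return base + added, intent
    markers = _sample_terms(rng, lexicon.upf_markers, int(rng.integers(1, 4)))
    return base + added + markers, intent


def generate_products(
    spec: GeneratorSpec, lexicon: Optional[IngredientLexicon] = None
) -> ProductSet:
    """Generate a raw, uncurated Mintel-like product set.

    Deterministic for a fixed seed.  Duplicate products are emitted
    immediately after their original, verbatim except for the product id
    and package descriptor.
    """
    lexicon = lexicon or default_lexicon()
    products: list[Product] = []
    for i in range(spec.n_products):
        rng = _rng_for(spec.seed, i)
        category = _choice(rng, spec.category_mix)
        subs = spec.subcategories[category]
        subcategory = subs[int(rng.integers(len(subs)))]
        is_beverage = category == "Beverages"
        year = int(rng.integers(2015, 2022))
        blank = rng.random() < spec.no_nutrient_rate
        basis = Basis.PER_100_ML if is_beverage else Basis.PER_100_G
        panel = NutrientPanel(basis=basis) if blank else _draw_panel(rng, spec, category)
        ingredients, _ = _build_ingredients(rng, spec, lexicon, category)
        product = Product(
            product_id=f"P{i:06d}",
            name=f"{subcategory} {i}",
            launch_year=year,
            market_category=category,
            market_subcategory=subcategory,
            is_beverage=is_beverage,
            ingredients=tuple(ingredients),
            panel=panel,
            package_descriptor="bottle" if is_beverage else "pack",
        )
        products.append(product)
        if rng.random() < spec.duplicate_rate:
            products.append(
                product.model_copy(
                    update={
                        "product_id": f"P{i:06d}D",
                        "package_descriptor": product.package_descriptor + " (multipack)",
                    }
                )
            )
    return ProductSet(products, provenance=f"synthetic(seed={spec.seed}, n={spec.n_products})")


# ---------------------------------------------------------------------------
# labeled benchmark construction

_HEALTHY_MARGIN = 0.9   # healthy values sit 10% inside every upper limit
_LOWER_MARGIN = 1.1     # ... and 10% above every lower limit
_VIOLATE_MARGIN = 1.25  # unhealthy values sit 25% outside


def _score_rule_bounds(rule: ScoreRule) -> tuple[tuple[str, float], tuple[str, float]]:
    """(full-points condition, zero-points condition) for a score rule.

    Conditions are ("le", x) — value must be <= x — or ("gt", x).
    """
    if rule.bands[0][1] == rule.max_points:
        full = ("le", rule.bands[0][0])
    elif rule.above_points == rule.max_points:
        full = ("gt", rule.bands[-1][0])
    else:
        raise GenerationError(
            f"score rule for {rule.nutrient!r} has no full-points region"
        )
    if rule.above_points == 0:
        zero = ("gt", rule.bands[-1][0])
    else:
        zero_bands = [b for b, p in rule.bands if p == 0]
        if not zero_bands:
            raise GenerationError(
                f"score rule for {rule.nutrient!r} has no zero-points region"
            )
        zero = ("le", zero_bands[-1])
    return full, zero


def _collect_constraints(
    probe: Product, rulesets: dict[System, RuleSet]
) -> tuple[dict[str, list[tuple[str, float]]], dict[str, list[tuple[str, float]]], set[str], dict[System, Optional[str]], bool]:
    """Per-nutrient healthy and unhealthy conditions for a probe product.

    Returns (healthy_conditions, unhealthy_conditions, required_nutrients,
    per-system category, doh_auto_prohibited).
    """
    healthy: dict[str, list[tuple[str, float]]] = {}
    unhealthy: dict[str, list[tuple[str, float]]] = {}
    required: set[str] = set()
    categories: dict[System, Optional[str]] = {}
    auto_prohibited = False

    for system, rs in rulesets.items():
        cat = assign_system_category(probe, rs)
        categories[system] = cat
        if cat is None:
            continue
        if rs.category_rule(cat).auto_prohibited:
            auto_prohibited = True
            continue
        required.update(rs.required_nutrients.get(cat, ()))
        crit = rs.criteria.get(cat)
        if crit is None:
            continue
        for c in crit.thresholds + crit.marketing:
            if c.comparator in (Comparator.LE, Comparator.LT):
                healthy.setdefault(c.nutrient, []).append(("le", c.threshold))
                unhealthy.setdefault(c.nutrient, []).append(("gt", c.threshold))
            else:
                healthy.setdefault(c.nutrient, []).append(("ge", c.threshold))
                unhealthy.setdefault(c.nutrient, []).append(("lt", c.threshold))
        for rule in crit.scores:
            full, zero = _score_rule_bounds(rule)
            healthy.setdefault(rule.nutrient, []).append(
                ("le", full[1]) if full[0] == "le" else ("ge", full[1] * _LOWER_MARGIN)
            )
            unhealthy.setdefault(rule.nutrient, []).append(
                ("gt", zero[1]) if zero[0] == "gt" else ("lt", zero[1] * 0.9)
            )
    return healthy, unhealthy, required, categories, auto_prohibited


def _resolve_value(
    conditions: list[tuple[str, float]], margin_up: float, margin_down: float, label: str
) -> float:
    """One value satisfying all conditions, with a safety margin.

    "le"/"lt" conditions cap the value (scaled by ``margin_down``),
    "ge"/"gt" conditions floor it (scaled by ``margin_up``).
    """
    uppers = [t for op, t in conditions if op in ("le", "lt")]
    lowers = [t for op, t in conditions if op in ("ge", "gt")]
    hi = min(uppers) * margin_down if uppers else None
    lo = max(lowers) * margin_up if lowers else None
    if lo is not None and lo == 0:
        lo = 0.1  # strictly-above-zero floor
    if hi is not None and lo is not None and lo > hi:
        raise GenerationError(
            f"unsatisfiable constraints for {label}: floor {lo} exceeds cap {hi}"
        )
    if hi is not None:
        return round(hi, 3)
    if lo is not None:
        return round(lo, 3)
    raise GenerationError(f"no constraints to resolve for {label}")


def _benchmark_panel(
    rng: np.random.Generator,
    spec: GeneratorSpec,
    category: str,
    healthy_intent: bool,
    rulesets: dict[System, RuleSet],
    probe: Product,
) -> tuple[NutrientPanel, dict[System, Optional[str]], bool]:
    healthy_c, unhealthy_c, required, categories, auto_prohibited = _collect_constraints(
        probe, rulesets
    )
    conditions = healthy_c if healthy_intent else unhealthy_c
    margin_up = _LOWER_MARGIN if healthy_intent else _VIOLATE_MARGIN
    margin_down = _HEALTHY_MARGIN if healthy_intent else 0.5
    values: dict[str, float] = {}
    for nutrient, conds in conditions.items():
        if healthy_intent:
            values[nutrient] = _resolve_value(conds, _LOWER_MARGIN, _HEALTHY_MARGIN, nutrient)
        else:
            # violate: push above every cap, or below every floor
            uppers = [t for op, t in conds if op in ("gt",)]
            lowers = [t for op, t in conds if op in ("lt",)]
            if uppers:
                values[nutrient] = round(max(uppers) * _VIOLATE_MARGIN, 3)
            elif lowers:
                values[nutrient] = round(min(lowers) * 0.5, 3)
    # fill remaining required nutrients with typical draws
    dists = spec.nutrient_distributions[category]
    for nutrient in required:
        if nutrient not in values:
            median, sigma = dists.get(nutrient, (1.0, 0.5))
            values[nutrient] = float(np.round(median * np.exp(sigma * rng.standard_normal()), 2))
    # panel invariants
    if "saturated_fat" in values:
        values.setdefault("total_fat", values["saturated_fat"] * 2)
        values["saturated_fat"] = min(values["saturated_fat"], values["total_fat"])
    if "added_sugars" in values:
        values.setdefault("total_sugars", values["added_sugars"])
        values["added_sugars"] = min(values["added_sugars"], values["total_sugars"])
    basis = Basis.PER_100_ML if category == "Beverages" else Basis.PER_100_G
    fiber = values.pop("fiber", None)
    panel = NutrientPanel(
        basis=basis,
        fiber=fiber,
        fiber_declared=fiber is not None,
        **values,
    )
    return panel, categories, auto_prohibited


def _benchmark_ingredients(
    rng: np.random.Generator, lexicon: IngredientLexicon, category: str
) -> tuple[list[str], NovaClass]:
    u = rng.random()
    if category == "Fats & Oils" and u < 0.5:
        return _sample_terms(rng, lexicon.pci_substances, int(rng.integers(1, 3))), NovaClass.PCI
    base = _sample_terms(rng, lexicon.whole_foods, int(rng.integers(2, 6)))
    if u < 0.6:
        markers = _sample_terms(rng, lexicon.upf_markers, int(rng.integers(1, 4)))
        return base + markers, NovaClass.UPF
    if u < 0.8:
        return base + _sample_terms(rng, lexicon.preservation_or_added_terms, 1), NovaClass.P
    return base, NovaClass.MP


def generate_labeled_benchmark(
    spec: GeneratorSpec,
    rulesets: Optional[dict[System, RuleSet]] = None,
    lexicon: Optional[IngredientLexicon] = None,
) -> LabeledBenchmark:
    """Generate products with attainable intended labels plus a truth table.

    Benchmark products always declare every nutrient the rulesets require
    (including fiber) and always carry an ingredient list: the benchmark
    probes label recovery, not missing-data handling.

    Raises
    ------
    GenerationError
        If an intended label is unattainable under the supplied configs
        (e.g. contradictory thresholds); the message names the product.
    """
    if rulesets is None:
        rulesets = {s: default_ruleset(s) for s in System}
    lexicon = lexicon or default_lexicon()
    products: list[Product] = []
    truth: dict[str, dict[str, str]] = {}
    for i in range(spec.n_products):
        rng = _rng_for(spec.seed, i)
        category = _choice(rng, spec.category_mix)
        subs = spec.subcategories[category]
        subcategory = subs[int(rng.integers(len(subs)))]
        is_beverage = category == "Beverages"
        healthy_intent = rng.random() < spec.healthy_rate
        pid = f"B{i:06d}"
        probe = Product(
            product_id=pid,
            market_category=category,
            market_subcategory=subcategory,
            is_beverage=is_beverage,
            panel=NutrientPanel(
                basis=Basis.PER_100_ML if is_beverage else Basis.PER_100_G
            ),
        )
        try:
            panel, categories, auto_prohibited = _benchmark_panel(
                rng, spec, category, healthy_intent, rulesets, probe
            )
        except GenerationError as err:
            raise GenerationError(f"product {pid} ({category}/{subcategory}): {err}") from err
        ingredients, nova_intent = _benchmark_ingredients(rng, lexicon, category)
        product = probe.model_copy(
            update={
                "name": f"{subcategory} benchmark {i}",
                "launch_year": int(rng.integers(2015, 2022)),
                "ingredients": tuple(ingredients),
                "panel": panel,
                "package_descriptor": "pack",
            }
        )
        products.append(product)
        entry: dict[str, str] = {"NOVA": nova_intent.value}
        for system in (System.DOH, System.WHO_SEA, System.HCL):
            cat = categories[system]
            if cat is None:
                entry[system.value] = "not_classifiable"
            elif system is System.DOH and auto_prohibited and rulesets[system].category_rule(cat).auto_prohibited:
                entry[system.value] = "unhealthy"
            else:
                entry[system.value] = "healthy" if healthy_intent else "unhealthy"
        truth[pid] = entry
    return LabeledBenchmark(
        products=ProductSet(
            products, provenance=f"benchmark(seed={spec.seed}, n={spec.n_products})"
        ),
        truth=truth,
    )
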