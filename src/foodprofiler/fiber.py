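"""Four-step fiber estimation for products missing a declared value.

Fiber is not a mandatory label nutrient, yet two of the profiling systems
require it, so undeclared values are estimated, in fixed precedence:

1. product's subcategory typically contains no fiber -> 0;
2. ingredient list contains no fiber-bearing ingredient -> 0;
3. subcategory holds similar-type products and has declared, non-zero
   values -> their arithmetic mean;
4. otherwise match to the most similar product with declared fiber
   (same subcategory, maximal ingredient-token Jaccard overlap above a
   configurable floor; ties keep the earliest donor) -> donor's value;
5. otherwise a conservative constant (default 1 g/100 g).

Declared values are never overwritten; every imputed value carries
``fiber_declared=False`` so a second pass reproduces the same result.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from sklearn.base import BaseEstimator, TransformerMixin

from .nova import normalize_term, parse_ingredient_list, term_matches
from .products import Product, ProductSet

__all__ = [
    "FiberImputationConfig",
    "ImputationReport",
    "FiberImputer",
    "impute_fiber",
    "default_fiber_config",
]


class FiberImputationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    zero_fiber_subcategories: tuple[str, ...] = ()
    fiber_ingredient_terms: tuple[str, ...] = ()
    averaging_subcategories: tuple[str, ...] = ()
    min_ingredient_overlap: float = Field(default=0.5, ge=0, le=1)
    fallback_value: float = Field(default=1.0, gt=0)

    @model_validator(mode="before")
    @classmethod
    def _normalize(cls, data):
        if isinstance(data, dict):
            for key in (
                "zero_fiber_subcategories",
                "fiber_ingredient_terms",
                "averaging_subcategories",
            ):
                if key in data and data[key] is not None:
                    data[key] = tuple(normalize_term(t) for t in data[key])
        return data


class ImputationReport(BaseModel):
    """Rule-application counts; the six counts partition the input."""

    n_declared_kept: int = 0
    n_zeroed: int = 0
    n_no_fiber_ingredient_zeroed: int = 0
    n_averaged: int = 0
    n_matched: int = 0
    n_fallback: int = 0

    @property
    def total(self) -> int:
        return (
            self.n_declared_kept
            + self.n_zeroed
            + self.n_no_fiber_ingredient_zeroed
            + self.n_averaged
            + self.n_matched
            + self.n_fallback
        )


def default_fiber_config() -> FiberImputationConfig:
    ref = resources.files("foodprofiler.fixtures") / "fiber_config.yaml"
    return FiberImputationConfig.model_validate(
        yaml.safe_load(ref.read_text(encoding="utf-8"))
    )


def _tokens(product: Product) -> frozenset[str]:
    out: list[str] = []
    for raw in product.ingredients:
        out.extend(parse_ingredient_list(raw))
    return frozenset(out)


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


class FiberImputer(BaseEstimator, TransformerMixin):
    """Estimator interface to the fiber estimation procedure.

    ``fit`` learns subcategory statistics from products with *declared*
    fiber: per-subcategory means of the declared non-zero values, and the
    per-subcategory donor pool for similarity matching.  ``transform``
    applies the five-rule cascade and records an :class:`ImputationReport`
    as ``report_``.
    """

    def __init__(self, config: Union[FiberImputationConfig, str, Path, None] = None):
        self.config = config

    def fit(self, X: ProductSet, y=None) -> "FiberImputer":
        cfg = self.config
        if cfg is None:
            cfg = default_fiber_config()
        elif isinstance(cfg, (str, Path)):
            cfg = FiberImputationConfig.model_validate(
                yaml.safe_load(Path(cfg).read_text(encoding="utf-8"))
            )
        self.config_ = cfg
        means: dict[str, list[float]] = {}
        donors: dict[str, list[tuple[frozenset[str], float]]] = {}
        for p in X:
            if not p.panel.fiber_declared:
                continue
            sub = normalize_term(p.market_subcategory)
            fiber = p.panel.fiber
            donors.setdefault(sub, []).append((_tokens(p), fiber))
            if fiber > 0:
                means.setdefault(sub, []).append(fiber)
        self.subcategory_means_ = {
            sub: sum(v) / len(v) for sub, v in means.items()
        }
        self.donors_ = donors
        return self

    def transform(self, X: ProductSet) -> ProductSet:
        cfg = self.config_
        report = {
            "n_declared_kept": 0,
            "n_zeroed": 0,
            "n_no_fiber_ingredient_zeroed": 0,
            "n_averaged": 0,
            "n_matched": 0,
            "n_fallback": 0,
        }
        out: list[Product] = []
        for p in X:
            if p.panel.fiber_declared:
                report["n_declared_kept"] += 1
                out.append(p)
                continue
            value, rule = self._impute_one(p)
            report[rule] += 1
            panel = p.panel.model_copy(update={"fiber": value, "fiber_declared": False})
            out.append(p.model_copy(update={"panel": panel}))
        self.report_ = ImputationReport(**report)
        return ProductSet(out, provenance=X.provenance + " (fiber imputed)")

    def _impute_one(self, p: Product) -> tuple[float, str]:
        cfg = self.config_
        sub = normalize_term(p.market_subcategory)
        if sub in cfg.zero_fiber_subcategories:
            return 0.0, "n_zeroed"
        toks = _tokens(p)
        has_fiber_ingredient = any(
            any(term_matches(term, t) for term in cfg.fiber_ingredient_terms)
            for t in toks
        )
        if not has_fiber_ingredient:
            return 0.0, "n_no_fiber_ingredient_zeroed"
        if sub in cfg.averaging_subcategories and sub in self.subcategory_means_:
            return self.subcategory_means_[sub], "n_averaged"
        best: Optional[tuple[float, int, float]] = None  # (-overlap proxy) keep max
        for idx, (donor_toks, donor_fiber) in enumerate(self.donors_.get(sub, [])):
            overlap = _jaccard(toks, donor_toks)
            if overlap < cfg.min_ingredient_overlap:
                continue
            if best is None or overlap > best[0]:
                best = (overlap, idx, donor_fiber)
        if best is not None:
            return best[2], "n_matched"
        return cfg.fallback_value, "n_fallback"


def impute_fiber(
    products: ProductSet,
    config: Union[FiberImputationConfig, str, Path, None] = None,
) -> tuple[ProductSet, ImputationReport]:
    """Impute undeclared fiber values; returns (new set, rule-count report)."""
    imputer = FiberImputer(config).fit(products)
    imputed = imputer.transform(products)
    return imputed, imputer.report_
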