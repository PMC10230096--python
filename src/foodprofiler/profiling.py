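"""Config-driven nutrient-profiling engines.

Three rule systems share one configuration schema:

* **DOH** — per-category point scores: each score rule awards the points of
  the first band whose upper bound covers the nutrient value; the overall
  score (percent of the category maximum) maps to Group A (>= c_A), Group B
  (c_B <= score < c_A) or Group C.  Some categories are automatically
  prohibited from marketing; a separate marketing-criteria layer is
  evaluated independently of the group label.
* **WHO SEA** — fail-any thresholds: exceeding any one of the category's
  limits prohibits marketing ("exceed" is a strict ``>``; equality passes).
* **HCL** — front-of-pack logo eligibility: every criterion of the
  category must hold.

Engines are pure functions of (product, ruleset).  A product whose market
category matches no rule, whose declared basis contradicts its
beverage/solid type, or which is missing a required nutrient, is
``NOT_CLASSIFIABLE``.
"""

from __future__ import annotations

from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from sklearn.base import BaseEstimator

from .products import NUTRIENT_FIELDS, Basis, Product

__all__ = [
    "System",
    "Comparator",
    "MatchPattern",
    "CategoryRule",
    "NutrientCriterion",
    "ScoreRule",
    "CategoryCriteria",
    "RuleSet",
    "DOHLabel",
    "WHOSEALabel",
    "HCLLabel",
    "ClassificationResult",
    "load_ruleset",
    "dump_ruleset",
    "default_ruleset",
    "assign_system_category",
    "classify_doh",
    "classify_whosea",
    "classify_hcl",
    "DOHClassifier",
    "WHOSEAClassifier",
    "HCLClassifier",
]


class System(str, Enum):
    DOH = "DOH"
    WHO_SEA = "WHO_SEA"
    HCL = "HCL"


class Comparator(str, Enum):
    """Pass condition of a criterion: value <comparator> threshold."""

    LE = "<="
    LT = "<"
    GE = ">="
    GT = ">"

    def passes(self, value: float, threshold: float) -> bool:
        if self is Comparator.LE:
            return value <= threshold
        if self is Comparator.LT:
            return value < threshold
        if self is Comparator.GE:
            return value >= threshold
        return value > threshold


class MatchPattern(BaseModel):
    """Literal match over (market_category, market_subcategory, is_beverage).

    Every provided key must match (case-insensitively for text); keys left
    unset are wildcards.
    """

    model_config = ConfigDict(frozen=True)

    category: Optional[str] = None
    subcategory: Optional[str] = None
    beverage: Optional[bool] = None

    @model_validator(mode="after")
    def _non_empty(self) -> "MatchPattern":
        if self.category is None and self.subcategory is None and self.beverage is None:
            raise ValueError("empty match pattern")
        return self

    def matches(self, product: Product) -> bool:
        if (
            self.category is not None
            and product.market_category.strip().casefold() != self.category.strip().casefold()
        ):
            return False
        if (
            self.subcategory is not None
            and product.market_subcategory.strip().casefold()
            != self.subcategory.strip().casefold()
        ):
            return False
        if self.beverage is not None and product.is_beverage != self.beverage:
            return False
        return True


class CategoryRule(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    match: tuple[MatchPattern, ...] = ()
    auto_prohibited: bool = False

    @model_validator(mode="after")
    def _patterns_present(self) -> "CategoryRule":
        if not self.match and not self.auto_prohibited:
            raise ValueError(f"category {self.name!r} has no match patterns")
        return self


class NutrientCriterion(BaseModel):
    model_config = ConfigDict(frozen=True)

    nutrient: str
    comparator: Comparator
    threshold: float = Field(ge=0)

    @model_validator(mode="after")
    def _known_nutrient(self) -> "NutrientCriterion":
        if self.nutrient not in NUTRIENT_FIELDS:
            raise ValueError(f"unknown nutrient {self.nutrient!r}")
        return self

    def passes(self, value: float) -> bool:
        return self.comparator.passes(value, self.threshold)


class ScoreRule(BaseModel):
    """Banded point award for one nutrient.

    ``bands`` is an ascending list of (upper bound, points): the value earns
    the points of the first band whose bound covers it, or ``above_points``
    beyond the last bound.  Descending point profiles score limit nutrients;
    ascending profiles (with ``above_points == max_points``) score nutrients
    to encourage, such as fiber or protein.
    """

    model_config = ConfigDict(frozen=True)

    nutrient: str
    bands: tuple[tuple[float, float], ...]
    max_points: float = Field(gt=0)
    above_points: float = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _validate(self) -> "ScoreRule":
        if self.nutrient not in NUTRIENT_FIELDS:
            raise ValueError(f"unknown nutrient {self.nutrient!r}")
        if not self.bands:
            raise ValueError("score rule needs at least one band")
        bounds = [b for b, _ in self.bands]
        if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
            raise ValueError(f"bands for {self.nutrient!r} not strictly ascending")
        for _, pts in self.bands:
            if pts < 0 or pts > self.max_points:
                raise ValueError(f"band points for {self.nutrient!r} outside [0, max_points]")
        if self.above_points > self.max_points:
            raise ValueError(f"above_points for {self.nutrient!r} exceeds max_points")
        return self

    def award(self, value: float) -> float:
        for bound, points in self.bands:
            if value <= bound:
                return points
        return self.above_points


class CategoryCriteria(BaseModel):
    """Per-category criteria: thresholds (WHO SEA/HCL) or scores (DOH)."""

    model_config = ConfigDict(frozen=True)

    thresholds: tuple[NutrientCriterion, ...] = ()
    scores: tuple[ScoreRule, ...] = ()
    marketing: tuple[NutrientCriterion, ...] = ()


class Cutpoints(BaseModel):
    model_config = ConfigDict(frozen=True)

    group_a: float = 80
    group_b: float = 60

    @model_validator(mode="after")
    def _ordered(self) -> "Cutpoints":
        if not self.group_a > self.group_b:
            raise ValueError("group_a cutpoint must exceed group_b cutpoint")
        return self


class RuleSet(BaseModel):
    model_config = ConfigDict(frozen=True)

    system: System
    categories: tuple[CategoryRule, ...]
    criteria: dict[str, CategoryCriteria] = {}
    required_nutrients: dict[str, tuple[str, ...]] = {}
    cutpoints: Cutpoints = Cutpoints()
    note: str = ""

    @model_validator(mode="after")
    def _cross_validate(self) -> "RuleSet":
        names = {c.name for c in self.categories}
        for key in self.criteria:
            if key not in names:
                raise ValueError(f"criteria for unknown category {key!r}")
        for key, nutrients in self.required_nutrients.items():
            if key not in names:
                raise ValueError(f"required_nutrients for unknown category {key!r}")
            for n in nutrients:
                if n not in NUTRIENT_FIELDS:
                    raise ValueError(f"unknown required nutrient {n!r} in {key!r}")
        if self.system is System.DOH:
            for key, crit in self.criteria.items():
                if not crit.scores:
                    raise ValueError(f"DOH category {key!r} has no score rules")
        else:
            for key, crit in self.criteria.items():
                if not crit.thresholds:
                    raise ValueError(f"{self.system.value} category {key!r} has no thresholds")
        return self

    def category_rule(self, name: str) -> CategoryRule:
        for c in self.categories:
            if c.name == name:
                return c
        raise KeyError(name)


class DOHLabel(str, Enum):
    GROUP_A = "GROUP_A"
    GROUP_B = "GROUP_B"
    GROUP_C = "GROUP_C"
    AUTO_PROHIBITED = "AUTO_PROHIBITED"
    NOT_CLASSIFIABLE = "NOT_CLASSIFIABLE"


class WHOSEALabel(str, Enum):
    PERMITTED = "PERMITTED"
    PROHIBITED = "PROHIBITED"
    NOT_CLASSIFIABLE = "NOT_CLASSIFIABLE"


class HCLLabel(str, Enum):
    ELIGIBLE = "ELIGIBLE"
    NOT_ELIGIBLE = "NOT_ELIGIBLE"
    NOT_CLASSIFIABLE = "NOT_CLASSIFIABLE"


class ClassificationResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    system: System
    system_category: Optional[str] = None
    label: str
    score_percent: Optional[float] = None
    marketing_permitted: Optional[bool] = None
    failed_criteria: tuple[str, ...] = ()


def load_ruleset(path: Union[str, Path]) -> RuleSet:
    """Load and validate a ruleset config file (YAML).

    Schema violations raise pydantic ``ValidationError`` carrying the path
    to the offending key.
    """
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return RuleSet.model_validate(data)


def dump_ruleset(ruleset: RuleSet, path: Union[str, Path]) -> None:
    data = ruleset.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


_FIXTURE_FILES = {
    System.DOH: "doh.yaml",
    System.WHO_SEA: "whosea.yaml",
    System.HCL: "hcl.yaml",
}


def default_ruleset(system: Union[System, str]) -> RuleSet:
    """The packaged fixture ruleset for a system (test values, not official)."""
    system = System(system)
    ref = resources.files("foodprofiler.fixtures") / _FIXTURE_FILES[system]
    return RuleSet.model_validate(yaml.safe_load(ref.read_text(encoding="utf-8")))


def assign_system_category(product: Product, ruleset: RuleSet) -> Optional[str]:
    """First category rule (in config order) matching the product, else None."""
    for rule in ruleset.categories:
        if any(p.matches(product) for p in rule.match):
            return rule.name
    return None


def _basis_consistent(product: Product) -> bool:
    expected = Basis.PER_100_ML if product.is_beverage else Basis.PER_100_G
    return product.panel.basis is expected


def _missing_required(product: Product, ruleset: RuleSet, category: str) -> bool:
    required = ruleset.required_nutrients.get(category, ())
    return any(product.panel.value(n) is None for n in required)


class _RuleBasedClassifier(BaseEstimator):
    """Shared scaffolding for the profiling engines.

    ``fit`` validates the ruleset (loading the packaged fixture when
    ``ruleset`` is None, or a file when given a path) and binds it as
    ``ruleset_``; ``predict`` maps products to label strings; ``classify``
    returns the full per-product result.
    """

    system: System

    def __init__(self, ruleset: Union[RuleSet, str, Path, None] = None):
        self.ruleset = ruleset

    def fit(self, X=None, y=None) -> "_RuleBasedClassifier":
        rs = self.ruleset
        if rs is None:
            rs = default_ruleset(self.system)
        elif isinstance(rs, (str, Path)):
            rs = load_ruleset(rs)
        if rs.system is not self.system:
            raise ValueError(
                f"{type(self).__name__} requires a {self.system.value} ruleset, "
                f"got {rs.system.value}"
            )
        self.ruleset_ = rs
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "ruleset_"):
            self.fit()

    def classify(self, product: Product) -> ClassificationResult:
        raise NotImplementedError

    def predict(self, X) -> "list[str]":
        self._check_fitted()
        return [self.classify(p).label for p in X]


class DOHClassifier(_RuleBasedClassifier):
    """Three-group DOH-style scorer with auto-prohibited categories."""

    system = System.DOH

    def classify(self, product: Product) -> ClassificationResult:
        self._check_fitted()
        rs = self.ruleset_
        if not _basis_consistent(product):
            return ClassificationResult(
                system=self.system, label=DOHLabel.NOT_CLASSIFIABLE.value
            )
        category = assign_system_category(product, rs)
        if category is None:
            return ClassificationResult(
                system=self.system, label=DOHLabel.NOT_CLASSIFIABLE.value
            )
        if rs.category_rule(category).auto_prohibited:
            return ClassificationResult(
                system=self.system,
                system_category=category,
                label=DOHLabel.AUTO_PROHIBITED.value,
                marketing_permitted=False,
            )
        if _missing_required(product, rs, category):
            return ClassificationResult(
                system=self.system,
                system_category=category,
                label=DOHLabel.NOT_CLASSIFIABLE.value,
            )
        crit = rs.criteria[category]
        total_max = sum(r.max_points for r in crit.scores)
        awarded = 0.0
        for rule in crit.scores:
            value = product.panel.value(rule.nutrient)
            if value is None:
                # nutrient outside the required list: score as zero points
                continue
            awarded += rule.award(value)
        score = 100.0 * awarded / total_max
        if score >= rs.cutpoints.group_a:
            label = DOHLabel.GROUP_A
        elif score >= rs.cutpoints.group_b:
            label = DOHLabel.GROUP_B
        else:
            label = DOHLabel.GROUP_C
        failed = tuple(
            c.nutrient
            for c in crit.marketing
            if product.panel.value(c.nutrient) is None
            or not c.passes(product.panel.value(c.nutrient))
        )
        return ClassificationResult(
            system=self.system,
            system_category=category,
            label=label.value,
            score_percent=score,
            marketing_permitted=not failed,
            failed_criteria=failed,
        )


class WHOSEAClassifier(_RuleBasedClassifier):
    """Fail-any threshold model: one exceedance prohibits marketing."""

    system = System.WHO_SEA

    def classify(self, product: Product) -> ClassificationResult:
        self._check_fitted()
        rs = self.ruleset_
        if not _basis_consistent(product):
            return ClassificationResult(
                system=self.system, label=WHOSEALabel.NOT_CLASSIFIABLE.value
            )
        category = assign_system_category(product, rs)
        if category is None or _missing_required(product, rs, category):
            return ClassificationResult(
                system=self.system,
                system_category=category,
                label=WHOSEALabel.NOT_CLASSIFIABLE.value,
            )
        failed = []
        for c in rs.criteria[category].thresholds:
            value = product.panel.value(c.nutrient)
            if value is not None and not c.passes(value):
                failed.append(c.nutrient)
        label = WHOSEALabel.PROHIBITED if failed else WHOSEALabel.PERMITTED
        return ClassificationResult(
            system=self.system,
            system_category=category,
            label=label.value,
            failed_criteria=tuple(failed),
        )


class HCLClassifier(_RuleBasedClassifier):
    """Logo eligibility: the conjunction of all category criteria."""

    system = System.HCL

    def classify(self, product: Product) -> ClassificationResult:
        self._check_fitted()
        rs = self.ruleset_
        if not _basis_consistent(product):
            return ClassificationResult(
                system=self.system, label=HCLLabel.NOT_CLASSIFIABLE.value
            )
        category = assign_system_category(product, rs)
        if category is None or _missing_required(product, rs, category):
            return ClassificationResult(
                system=self.system,
                system_category=category,
                label=HCLLabel.NOT_CLASSIFIABLE.value,
            )
        failed = []
        for c in rs.criteria[category].thresholds:
            value = product.panel.value(c.nutrient)
            if value is not None and not c.passes(value):
                failed.append(c.nutrient)
        label = HCLLabel.NOT_ELIGIBLE if failed else HCLLabel.ELIGIBLE
        return ClassificationResult(
            system=self.system,
            system_category=category,
            label=label.value,
            failed_criteria=tuple(failed),
        )


def classify_doh(product: Product, ruleset: Optional[RuleSet] = None) -> ClassificationResult:
    return DOHClassifier(ruleset).fit().classify(product)


def classify_whosea(product: Product, ruleset: Optional[RuleSet] = None) -> ClassificationResult:
    return WHOSEAClassifier(ruleset).fit().classify(product)


def classify_hcl(product: Product, ruleset: Optional[RuleSet] = None) -> ClassificationResult:
    return HCLClassifier(ruleset).fit().classify(product)
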