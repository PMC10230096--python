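"""Product data model, CSV input/output, and sample curation.

A :class:`Product` is one packaged food or beverage: market category labels,
a per-100 g/ml nutrient panel, and an ordered ingredient list.  Curation
mirrors the construction of a market-launch analysis sample: drop products
with no nutrient information at all, drop exact duplicates (identical
nutrition and ingredients, packaging ignored), then drop excluded market
categories (non-food, alcoholic, supplementary products).
"""

from __future__ import annotations

import csv
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Basis",
    "NutrientPanel",
    "Product",
    "ProductSet",
    "CurationReport",
    "ProductCSVError",
    "NUTRIENT_FIELDS",
    "read_products",
    "write_products",
    "curate_products",
    "default_excluded_categories",
    "split_ingredient_field",
]

#: Canonical nutrient names, in the fixed CSV column order.
NUTRIENT_FIELDS: tuple[str, ...] = (
    "energy",
    "total_fat",
    "saturated_fat",
    "total_sugars",
    "added_sugars",
    "sodium",
    "protein",
    "fiber",
    "calcium",
    "iron",
    "riboflavin",
)

#: nutrient name -> CSV column carrying it (units encoded in the header).
_NUTRIENT_COLUMNS: dict[str, str] = {
    "energy": "energy_kcal",
    "total_fat": "fat_g",
    "saturated_fat": "satfat_g",
    "total_sugars": "sugars_g",
    "added_sugars": "added_sugars_g",
    "sodium": "sodium_mg",
    "protein": "protein_g",
    "fiber": "fiber_g",
    "calcium": "calcium_mg",
    "iron": "iron_mg",
    "riboflavin": "riboflavin_mg",
}

_CSV_COLUMNS: tuple[str, ...] = (
    "id",
    "name",
    "year",
    "category",
    "subcategory",
    "is_beverage",
    "basis",
    *_NUTRIENT_COLUMNS.values(),
    "fiber_declared",
    "ingredients",
    "package",
)


class Basis(str, Enum):
    """Reference amount of the nutrient declaration."""

    PER_100_G = "per_100_g"
    PER_100_ML = "per_100_ml"


class NutrientPanel(BaseModel):
    """Per-100 g/ml nutrient declaration; every value may be missing.

    ``None`` means *not declared*, which is distinct from a declared zero.
    ``fiber_declared`` is True only when the fiber value came from the
    input data; imputed fiber carries ``fiber_declared=False``.
    """

    model_config = ConfigDict(frozen=True)

    basis: Basis = Basis.PER_100_G
    energy: Optional[float] = Field(default=None, ge=0)
    total_fat: Optional[float] = Field(default=None, ge=0)
    saturated_fat: Optional[float] = Field(default=None, ge=0)
    total_sugars: Optional[float] = Field(default=None, ge=0)
    added_sugars: Optional[float] = Field(default=None, ge=0)
    sodium: Optional[float] = Field(default=None, ge=0)
    protein: Optional[float] = Field(default=None, ge=0)
    fiber: Optional[float] = Field(default=None, ge=0)
    fiber_declared: bool = False
    calcium: Optional[float] = Field(default=None, ge=0)
    iron: Optional[float] = Field(default=None, ge=0)
    riboflavin: Optional[float] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check_consistency(self) -> "NutrientPanel":
        if (
            self.saturated_fat is not None
            and self.total_fat is not None
            and self.saturated_fat > self.total_fat
        ):
            raise ValueError("saturated_fat exceeds total_fat")
        if (
            self.added_sugars is not None
            and self.total_sugars is not None
            and self.added_sugars > self.total_sugars
        ):
            raise ValueError("added_sugars exceeds total_sugars")
        if self.fiber is None and self.fiber_declared:
            raise ValueError("fiber_declared requires a fiber value")
        return self

    def value(self, nutrient: str) -> Optional[float]:
        if nutrient not in NUTRIENT_FIELDS:
            raise KeyError(f"unknown nutrient {nutrient!r}")
        return getattr(self, nutrient)

    @property
    def n_present(self) -> int:
        """Number of declared (non-missing) nutrient values."""
        return sum(self.value(n) is not None for n in NUTRIENT_FIELDS)


class Product(BaseModel):
    """One packaged product.

    ``ingredients`` preserves the declared order (descending predominance);
    an empty tuple means the ingredient list was not provided.
    """

    model_config = ConfigDict(frozen=True)

    product_id: str
    name: str = ""
    launch_year: Optional[int] = None
    market_category: str = ""
    market_subcategory: str = ""
    is_beverage: bool = False
    ingredients: tuple[str, ...] = ()
    panel: NutrientPanel = NutrientPanel()
    package_descriptor: str = ""

    def normalized_ingredients(self) -> tuple[str, ...]:
        return tuple(t.strip().casefold() for t in self.ingredients)


class ProductSet:
    """Ordered collection of products with unique ids."""

    def __init__(self, products: Iterable[Product] = (), provenance: str = ""):
        self.products: list[Product] = list(products)
        self.provenance = provenance
        seen: set[str] = set()
        for p in self.products:
            if p.product_id in seen:
                raise ValueError(f"duplicate product_id {p.product_id!r}")
            seen.add(p.product_id)

    def __len__(self) -> int:
        return len(self.products)

    def __iter__(self) -> Iterator[Product]:
        return iter(self.products)

    def __getitem__(self, i):
        return self.products[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, ProductSet) and self.products == other.products

    def __repr__(self) -> str:
        return f"ProductSet(n={len(self)}, provenance={self.provenance!r})"


class CurationReport(BaseModel):
    """Bookkeeping of the three curation stages.

    The invariant ``n_output = n_input - removals`` is enforced on
    construction, so any report that exists is internally consistent.
    """

    n_input: int = Field(ge=0)
    n_removed_no_nutrients: int = Field(ge=0)
    n_removed_duplicates: int = Field(ge=0)
    n_removed_excluded_category: int = Field(ge=0)
    n_output: int = Field(ge=0)

    @model_validator(mode="after")
    def _check_arithmetic(self) -> "CurationReport":
        expected = (
            self.n_input
            - self.n_removed_no_nutrients
            - self.n_removed_duplicates
            - self.n_removed_excluded_category
        )
        if self.n_output != expected:
            raise ValueError(
                f"n_output={self.n_output} inconsistent with stage removals "
                f"(expected {expected})"
            )
        return self


class ProductCSVError(ValueError):
    """Raised for malformed product CSV input."""


def split_ingredient_field(raw: str) -> tuple[str, ...]:
    """Split the serialized ingredient field into top-level tokens.

    Splits on ``;`` at parenthesis depth zero only, so sub-ingredient
    groups like ``"stabilizer (pectin; gum)"`` stay one raw token.
    """
    raw = raw.strip()
    if not raw:
        return ()
    tokens: list[str] = []
    depth = 0
    start = 0
    for i, ch in enumerate(raw):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(depth - 1, 0)
        elif ch == ";" and depth == 0:
            tokens.append(raw[start:i].strip())
            start = i + 1
    tokens.append(raw[start:].strip())
    return tuple(t for t in tokens if t)


def _parse_cell(row_index: int, column: str, cell: str) -> Optional[float]:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return float(cell)
    except ValueError:
        raise ProductCSVError(
            f"row {row_index}: non-numeric value {cell!r} in column {column!r}"
        ) from None


def _parse_bool(cell: str) -> bool:
    return cell.strip().lower() in {"1", "true", "yes", "y"}


def read_products(path: str | Path, dialect: Optional[dict] = None) -> ProductSet:
    """Read a product CSV into a :class:`ProductSet`.

    Empty cells map to missing values, never to zero.  The ``fiber_declared``
    column is optional; when absent, any present fiber value counts as
    declared.

    Raises
    ------
    ProductCSVError
        If a required column is missing from the header, or a nutrient
        cell is non-numeric (the message carries the 1-based data row).
    """
    opts = {"delimiter": ","}
    opts.update(dialect or {})
    path = Path(path)
    products: list[Product] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=opts["delimiter"])
        header = reader.fieldnames or []
        required = [c for c in _CSV_COLUMNS if c != "fiber_declared"]
        missing = [c for c in required if c not in header]
        if missing:
            raise ProductCSVError(f"missing column(s) in header: {', '.join(missing)}")
        for i, row in enumerate(reader, start=1):
            nutrients = {
                name: _parse_cell(i, col, row[col] or "")
                for name, col in _NUTRIENT_COLUMNS.items()
            }
            declared_cell = (row.get("fiber_declared") or "").strip()
            if declared_cell:
                fiber_declared = _parse_bool(declared_cell) and nutrients["fiber"] is not None
            else:
                fiber_declared = nutrients["fiber"] is not None
            year_cell = (row["year"] or "").strip()
            try:
                year = int(year_cell) if year_cell else None
            except ValueError:
                raise ProductCSVError(
                    f"row {i}: non-integer launch year {year_cell!r}"
                ) from None
            basis_cell = (row["basis"] or "").strip() or Basis.PER_100_G.value
            try:
                basis = Basis(basis_cell)
            except ValueError:
                raise ProductCSVError(f"row {i}: unknown basis {basis_cell!r}") from None
            products.append(
                Product(
                    product_id=row["id"],
                    name=row["name"] or "",
                    launch_year=year,
                    market_category=row["category"] or "",
                    market_subcategory=row["subcategory"] or "",
                    is_beverage=_parse_bool(row["is_beverage"] or ""),
                    ingredients=split_ingredient_field(row["ingredients"] or ""),
                    panel=NutrientPanel(
                        basis=basis, fiber_declared=fiber_declared, **nutrients
                    ),
                    package_descriptor=row["package"] or "",
                )
            )
    return ProductSet(products, provenance=str(path))


def _format_value(v: Optional[float]) -> str:
    if v is None:
        return ""
    return repr(v) if v != int(v) else str(int(v))


def write_products(products: ProductSet, path: str | Path) -> None:
    """Write a :class:`ProductSet` to CSV in the documented column order.

    Missing values serialize to empty cells; ingredient order is preserved
    via the "; " join.  ``read_products(write_products(S)) == S``.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for p in products:
            panel = p.panel
            writer.writerow(
                [
                    p.product_id,
                    p.name,
                    "" if p.launch_year is None else p.launch_year,
                    p.market_category,
                    p.market_subcategory,
                    int(p.is_beverage),
                    panel.basis.value,
                    *(_format_value(panel.value(n)) for n in NUTRIENT_FIELDS),
                    int(panel.fiber_declared),
                    "; ".join(p.ingredients),
                    p.package_descriptor,
                ]
            )


def default_excluded_categories() -> tuple[str, ...]:
    """Market categories removed by default at curation stage 3."""
    ref = resources.files("foodprofiler.fixtures") / "excluded_categories.yaml"
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return tuple(data["excluded_categories"])


def _dedup_key(p: Product):
    panel = p.panel
    return (
        panel.basis,
        tuple(panel.value(n) for n in NUTRIENT_FIELDS),
        p.normalized_ingredients(),
    )


def curate_products(
    products: ProductSet,
    excluded_categories: Optional[Sequence[str]] = None,
) -> tuple[ProductSet, CurationReport]:
    """Apply the three-stage curation filter, in fixed order.

    1. remove products whose panel declares no nutrient value at all;
    2. remove exact duplicates — identical nutrition (missing == missing)
       and identical normalized ingredient sequence; packaging ignored;
       the first occurrence in input order is kept;
    3. remove products whose market category is excluded (case-insensitive).

    Each stage is counted against the set entering that stage, so the
    report's arithmetic invariant holds by construction.
    """
    if excluded_categories is None:
        excluded_categories = default_excluded_categories()
    excluded = {c.strip().casefold() for c in excluded_categories}

    n_input = len(products)
    stage1 = [p for p in products if p.panel.n_present > 0]
    n_no_nutrients = n_input - len(stage1)

    seen: set = set()
    stage2: list[Product] = []
    for p in stage1:
        key = _dedup_key(p)
        if key in seen:
            continue
        seen.add(key)
        stage2.append(p)
    n_duplicates = len(stage1) - len(stage2)

    stage3 = [p for p in stage2 if p.market_category.strip().casefold() not in excluded]
    n_excluded = len(stage2) - len(stage3)

    report = CurationReport(
        n_input=n_input,
        n_removed_no_nutrients=n_no_nutrients,
        n_removed_duplicates=n_duplicates,
        n_removed_excluded_category=n_excluded,
        n_output=len(stage3),
    )
    return ProductSet(stage3, provenance=products.provenance + " (curated)"), report
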