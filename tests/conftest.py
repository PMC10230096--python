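import pytest

from foodprofiler import (
    Basis,
    NutrientPanel,
    Product,
    ProductSet,
    default_lexicon,
    default_ruleset,
)
from foodprofiler.profiling import System


@pytest.fixture(scope="session")
def doh_ruleset():
    return default_ruleset(System.DOH)


@pytest.fixture(scope="session")
def whosea_ruleset():
    return default_ruleset(System.WHO_SEA)


@pytest.fixture(scope="session")
def hcl_ruleset():
    return default_ruleset(System.HCL)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def make_product(
    pid="p1",
    category="Snacks",
    subcategory="Nuts",
    beverage=False,
    ingredients=(),
    **nutrients,
):
    """Compact product factory for rule-engine tests."""
    basis = Basis.PER_100_ML if beverage else Basis.PER_100_G
    fiber_declared = nutrients.get("fiber") is not None
    return Product(
        product_id=pid,
        name=pid,
        market_category=category,
        market_subcategory=subcategory,
        is_beverage=beverage,
        ingredients=tuple(ingredients),
        panel=NutrientPanel(basis=basis, fiber_declared=fiber_declared, **nutrients),
    )


@pytest.fixture
def product_factory():
    return make_product
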