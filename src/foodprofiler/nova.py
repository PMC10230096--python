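"""NOVA food-processing classification from ingredient lists.

The four NOVA groups order products by the extent and purpose of
industrial processing: unprocessed/minimally processed (MP), processed
culinary ingredients (PCI), processed (P), and ultra-processed (UPF).
A product is UPF when its ingredient list contains at least one marker —
a food substance of no (or rare) culinary use (maltodextrin, high fructose
corn syrup, protein isolates, modified starches, ...) or a cosmetic
additive class (flavors, colorants, emulsifiers, sweeteners, thickeners).
The decision cascade is fixed: UPF -> PCI -> P -> MP, and marker presence
dominates everything else.

Token-term matching is deliberately literal: a term matches a token when
it equals the token, occurs in it at word boundaries, or (for multi-word
terms) its words appear in order within the token's words, so
``modified starch`` matches ``modified corn starch``.  E-numbers are
matched by pattern (E followed by 3-4 digits) minus a configurable
allowlist.  There is no fuzzy matching.
"""

from __future__ import annotations

import re
import warnings
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, model_validator
from sklearn.base import BaseEstimator

from .products import Product

__all__ = [
    "NovaClass",
    "NovaResult",
    "IngredientLexicon",
    "default_lexicon",
    "load_lexicon",
    "parse_ingredient_list",
    "normalize_term",
    "term_matches",
    "classify_nova",
    "NovaClassifier",
]

_E_NUMBER = re.compile(r"\be\s?(\d{3,4})[a-z]?\b")
_PERCENT = re.compile(r"\d+(?:\.\d+)?\s*%")


class NovaClass(str, Enum):
    MP = "MP"
    PCI = "PCI"
    P = "P"
    UPF = "UPF"
    NOT_CLASSIFIABLE = "NOT_CLASSIFIABLE"


class NovaResult(BaseModel):
    """Class plus the marker terms that drove a UPF call (auditability)."""

    model_config = ConfigDict(frozen=True)

    nova_class: NovaClass
    matched_markers: tuple[str, ...] = ()


def normalize_term(term: str) -> str:
    term = _PERCENT.sub("", term)
    term = term.replace("*", " ")
    term = re.sub(r"\s+", " ", term)
    return term.strip(" .,:-").casefold()


class IngredientLexicon(BaseModel):
    """Term lists by role; all terms are normalized on construction."""

    model_config = ConfigDict(frozen=True)

    upf_markers: tuple[str, ...] = ()
    pci_substances: tuple[str, ...] = ()
    pci_categories: tuple[str, ...] = ()
    preservation_or_added_terms: tuple[str, ...] = ()
    e_number_allowlist: tuple[str, ...] = ()
    whole_foods: tuple[str, ...] = ()

    @model_validator(mode="before")
    @classmethod
    def _normalize(cls, data):
        if isinstance(data, dict):
            data = {
                k: tuple(normalize_term(t) for t in v) if isinstance(v, (list, tuple)) else v
                for k, v in data.items()
            }
        return data

    @model_validator(mode="after")
    def _disjoint(self) -> "IngredientLexicon":
        overlap = set(self.upf_markers) & set(self.pci_substances)
        if overlap:
            raise ValueError(f"upf_markers and pci_substances overlap: {sorted(overlap)}")
        return self


def load_lexicon(path: Union[str, Path]) -> IngredientLexicon:
    return IngredientLexicon.model_validate(
        yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    )


def default_lexicon() -> IngredientLexicon:
    """The packaged fixture lexicon (illustrative terms, not exhaustive)."""
    ref = resources.files("foodprofiler.fixtures") / "nova_lexicon.yaml"
    return IngredientLexicon.model_validate(yaml.safe_load(ref.read_text(encoding="utf-8")))


def parse_ingredient_list(raw: str) -> tuple[str, ...]:
    """Split raw ingredient text into ordered, normalized tokens.

    Splits on ``;`` and ``,`` outside parentheses; parenthesized
    sub-ingredient groups are parsed recursively and flattened directly
    after their parent token.  Percentage annotations are stripped.
    Unbalanced parentheses emit a warning and are handled best-effort.
    """
    if not raw or not raw.strip():
        return ()
    if raw.count("(") != raw.count(")"):
        warnings.warn("unbalanced parentheses in ingredient list; best-effort parse")
    return tuple(_parse_segments(raw))


def _parse_segments(text: str) -> list[str]:
    tokens: list[str] = []
    for segment in _split_top_level(text):
        parent, groups = _extract_groups(segment)
        parent_norm = normalize_term(parent)
        if parent_norm:
            tokens.append(parent_norm)
        for group in groups:
            tokens.extend(_parse_segments(group))
    return tokens


def _split_top_level(text: str) -> list[str]:
    parts: list[str] = []
    depth = 0
    start = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(depth - 1, 0)
        elif ch in ";," and depth == 0:
            parts.append(text[start:i])
            start = i + 1
    parts.append(text[start:])
    return [p for p in parts if p.strip()]


def _extract_groups(segment: str) -> tuple[str, list[str]]:
    """Remove top-level parenthesized groups; return (outside text, groups)."""
    outside: list[str] = []
    groups: list[str] = []
    depth = 0
    buf_start = 0
    group_start = 0
    for i, ch in enumerate(segment):
        if ch == "(":
            if depth == 0:
                outside.append(segment[buf_start:i])
                group_start = i + 1
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth == 0:
                groups.append(segment[group_start:i])
                buf_start = i + 1
            depth = max(depth, 0)
    if depth > 0:  # unbalanced: treat the dangling remainder as a group
        groups.append(segment[group_start:])
    else:
        outside.append(segment[buf_start:])
    return " ".join(outside), groups


def term_matches(term: str, token: str) -> bool:
    """Literal term-token match (both already normalized)."""
    if term == token:
        return True
    if re.search(rf"\b{re.escape(term)}\b", token):
        return True
    term_words = term.split()
    if len(term_words) > 1:
        token_words = token.split()
        it = iter(token_words)
        return all(w in it for w in term_words)
    return False


def _match_terms(token: str, terms: Iterable[str]) -> Optional[str]:
    for term in terms:
        if term_matches(term, token):
            return term
    return None


def _e_number_markers(token: str, allowlist: Iterable[str]) -> list[str]:
    allow = set(allowlist)
    return [
        m.group(0).replace(" ", "")
        for m in _E_NUMBER.finditer(token)
        if m.group(0).replace(" ", "") not in allow
    ]


class NovaClassifier(BaseEstimator):
    """Rule-based NOVA classifier over a marker lexicon.

    Parameters
    ----------
    lexicon : IngredientLexicon, path, or None
        None selects the packaged fixture lexicon.
    overrides : mapping product_id -> NovaClass, optional
        Manual adjudications; consulted before the rule cascade so a human
        review can be represented without changing the algorithm.
    """

    def __init__(
        self,
        lexicon: Union[IngredientLexicon, str, Path, None] = None,
        overrides: Optional[Mapping[str, Union[NovaClass, str]]] = None,
    ):
        self.lexicon = lexicon
        self.overrides = overrides

    def fit(self, X=None, y=None) -> "NovaClassifier":
        lex = self.lexicon
        if lex is None:
            lex = default_lexicon()
        elif isinstance(lex, (str, Path)):
            lex = load_lexicon(lex)
        self.lexicon_ = lex
        self.overrides_ = {
            pid: NovaClass(c) for pid, c in (self.overrides or {}).items()
        }
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "lexicon_"):
            self.fit()

    def tokens(self, product: Product) -> tuple[str, ...]:
        out: list[str] = []
        for raw in product.ingredients:
            out.extend(parse_ingredient_list(raw))
        return tuple(out)

    def classify_detailed(self, product: Product) -> NovaResult:
        self._check_fitted()
        lex = self.lexicon_
        if product.product_id in self.overrides_:
            return NovaResult(nova_class=self.overrides_[product.product_id])
        toks = self.tokens(product)
        if not toks:
            return NovaResult(nova_class=NovaClass.NOT_CLASSIFIABLE)
        markers: list[str] = []
        for tok in toks:
            hit = _match_terms(tok, lex.upf_markers)
            if hit:
                markers.append(hit)
            markers.extend(_e_number_markers(tok, lex.e_number_allowlist))
        if markers:
            return NovaResult(nova_class=NovaClass.UPF, matched_markers=tuple(dict.fromkeys(markers)))
        category_text = f"{product.market_category} {product.market_subcategory}".casefold()
        pci_category = any(
            term_matches(pat, category_text) for pat in lex.pci_categories
        )
        all_pci = all(_match_terms(t, lex.pci_substances) for t in toks)
        if pci_category and all_pci:
            return NovaResult(nova_class=NovaClass.PCI)
        if any(
            _match_terms(t, lex.pci_substances) or _match_terms(t, lex.preservation_or_added_terms)
            for t in toks
        ):
            return NovaResult(nova_class=NovaClass.P)
        return NovaResult(nova_class=NovaClass.MP)

    def classify(self, product: Product) -> NovaClass:
        return self.classify_detailed(product).nova_class

    def predict(self, X) -> "list[str]":
        self._check_fitted()
        return [self.classify(p).value for p in X]


def classify_nova(
    product: Product, lexicon: Optional[IngredientLexicon] = None
) -> NovaClass:
    """Assign the product's NOVA group (module-level convenience wrapper)."""
    return NovaClassifier(lexicon).fit().classify(product)
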