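"""Two-level comorbidity taxonomy and label-vector encoding.

The classification target is a two-level hierarchy: ``m`` top-level
comorbidity categories (e.g. hypertension, sleep-disordered breathing),
each with ``n_i`` clinical subtypes (e.g. pulmonary hypertension,
obstructive sleep apnoea).  Every prediction and gold annotation is a
binary vector of length ``d = m + sum(n_i)`` laid out as all parents in
taxonomy order followed by each parent's children contiguously.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "LexEntry",
    "Category",
    "Taxonomy",
    "LabelVector",
    "TaxonomyError",
    "load_taxonomy",
    "load_default_taxonomy",
    "dumps_taxonomy",
]

_LEX_KINDS = ("canonical", "abbreviation", "german", "proxy")


class TaxonomyError(ValueError):
    """Raised for malformed taxonomy configurations or unknown ids."""


@dataclass(frozen=True)
class LexEntry:
    """One surface form of a category: a term plus its variant kind."""

    term: str
    kind: str = "canonical"

    def __post_init__(self) -> None:
        if not self.term:
            raise TaxonomyError("lexicon entry with empty term")
        if self.kind not in _LEX_KINDS:
            raise TaxonomyError(
                f"lexicon kind {self.kind!r} not one of {_LEX_KINDS}"
            )


@dataclass(frozen=True)
class Category:
    """A node of the taxonomy: a top-level comorbidity or a subtype."""

    id: str
    display_name: str
    level: str  # "top" | "sub"
    parent_id: str | None = None
    lexicon: tuple[LexEntry, ...] = ()

    def __post_init__(self) -> None:
        if self.level not in ("top", "sub"):
            raise TaxonomyError(f"category {self.id!r}: bad level {self.level!r}")
        if self.level == "top" and self.parent_id is not None:
            raise TaxonomyError(f"top-level category {self.id!r} has a parent")
        if self.level == "sub" and self.parent_id is None:
            raise TaxonomyError(f"subcategory {self.id!r} lacks a parent")

    def terms(self, kinds: tuple[str, ...] | None = None) -> list[str]:
        """Surface forms, optionally restricted to the given variant kinds."""
        if kinds is None:
            return [e.term for e in self.lexicon]
        return [e.term for e in self.lexicon if e.kind in kinds]


@dataclass(frozen=True)
class Taxonomy:
    """Ordered two-level hierarchy with a fixed label-vector layout."""

    name: str
    top_categories: tuple[Category, ...]
    children: dict[str, tuple[Category, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.top_categories:
            raise TaxonomyError("taxonomy needs at least one top-level category")
        seen: set[str] = set()
        for cat in self.all_categories():
            if cat.id in seen:
                raise TaxonomyError(f"duplicate category id {cat.id!r}")
            seen.add(cat.id)
        top_ids = {c.id for c in self.top_categories}
        for pid, kids in self.children.items():
            if pid not in top_ids:
                raise TaxonomyError(
                    f"child group references unknown parent {pid!r}"
                )
            for kid in kids:
                if kid.parent_id != pid:
                    raise TaxonomyError(
                        f"child {kid.id!r} filed under {pid!r} but names "
                        f"parent {kid.parent_id!r}"
                    )

    # -- structure ---------------------------------------------------------

    @property
    def m(self) -> int:
        """Number of top-level categories."""
        return len(self.top_categories)

    def n_children(self, parent_id: str) -> int:
        return len(self.children.get(parent_id, ()))

    def dimension(self) -> int:
        """Total label-vector length d = m + sum(n_i)."""
        return self.m + sum(len(v) for v in self.children.values())

    def all_categories(self) -> list[Category]:
        """All categories in label-vector order: parents, then each
        parent's children contiguously in parent order."""
        out = list(self.top_categories)
        for parent in self.top_categories:
            out.extend(self.children.get(parent.id, ()))
        return out

    def sub_categories(self, parent_id: str) -> tuple[Category, ...]:
        if parent_id not in {c.id for c in self.top_categories}:
            raise TaxonomyError(f"unknown parent id {parent_id!r}")
        return self.children.get(parent_id, ())

    def get(self, category_id: str) -> Category:
        cat = self._index().get(category_id)
        if cat is None:
            raise TaxonomyError(f"unknown category id {category_id!r}")
        return cat

    def __contains__(self, category_id: str) -> bool:
        return category_id in self._index()

    def _index(self) -> dict[str, Category]:
        # rebuilt on demand; frozen dataclass cannot cache without hacks
        return {c.id: c for c in self.all_categories()}

    def position(self, category_id: str) -> int:
        """Index of a category's bit in the concatenated label vector."""
        for i, cat in enumerate(self.all_categories()):
            if cat.id == category_id:
                return i
        raise TaxonomyError(f"unknown category id {category_id!r}")

    # -- label vectors -----------------------------------------------------

    def encode_labels(self, positive_ids: set[str] | list[str]) -> "LabelVector":
        """Binary label vector with 1 exactly at the listed category ids."""
        order = [c.id for c in self.all_categories()]
        index = {cid: i for i, cid in enumerate(order)}
        bits = np.zeros(self.dimension(), dtype=np.int8)
        for cid in positive_ids:
            if cid not in index:
                raise TaxonomyError(f"unknown category id {cid!r}")
            bits[index[cid]] = 1
        return LabelVector(
            parent_bits=bits[: self.m].copy(),
            child_bits=bits[self.m :].copy(),
            taxonomy_ref=self.name,
        )

    def decode_labels(self, vec: "LabelVector") -> set[str]:
        """Set of category ids whose bit is 1."""
        bits = vec.bits
        if len(bits) != self.dimension():
            raise TaxonomyError(
                f"vector length {len(bits)} != taxonomy dimension "
                f"{self.dimension()}"
            )
        return {c.id for c, b in zip(self.all_categories(), bits) if b}


@dataclass(frozen=True)
class LabelVector:
    """Concatenated binary label vector: parent bits then child bits."""

    parent_bits: np.ndarray
    child_bits: np.ndarray
    taxonomy_ref: str = ""

    def __post_init__(self) -> None:
        for arr in (self.parent_bits, self.child_bits):
            if arr.ndim != 1:
                raise TaxonomyError("label bits must be one-dimensional")
            if not np.isin(arr, (0, 1)).all():
                raise TaxonomyError("label bits must be 0 or 1")

    @property
    def bits(self) -> np.ndarray:
        return np.concatenate([self.parent_bits, self.child_bits])

    def __len__(self) -> int:
        return len(self.parent_bits) + len(self.child_bits)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelVector):
            return NotImplemented
        return (
            len(self) == len(other)
            and bool(np.array_equal(self.bits, other.bits))
            and self.taxonomy_ref == other.taxonomy_ref
        )


# ---------------------------------------------------------------------------
# configuration I/O


def _parse_lexicon(raw: object, cat_id: str) -> tuple[LexEntry, ...]:
    if raw is None:
        return ()
    if not isinstance(raw, list):
        raise TaxonomyError(f"category {cat_id!r}: lexicon must be a list")
    entries = []
    for item in raw:
        if isinstance(item, str):
            entries.append(LexEntry(term=item))
        elif isinstance(item, dict):
            entries.append(
                LexEntry(
                    term=str(item.get("term", "")),
                    kind=str(item.get("kind", "canonical")),
                )
            )
        else:
            raise TaxonomyError(
                f"category {cat_id!r}: lexicon entry {item!r} must be a "
                "string or a {{term, kind}} mapping"
            )
    return tuple(entries)


def load_taxonomy(config_source: str, name: str = "taxonomy") -> Taxonomy:
    """Parse a YAML/JSON taxonomy configuration into a validated Taxonomy.

    Schema: ``{name?: str, categories: [{id, name, parent?, lexicon?}]}``.
    Category order in the file fixes the label-vector layout.  Duplicate
    ids and children naming an undefined parent are rejected.
    """
    try:
        doc = yaml.safe_load(config_source)
    except yaml.YAMLError as exc:
        raise TaxonomyError(f"taxonomy config does not parse: {exc}") from exc
    if not isinstance(doc, dict) or "categories" not in doc:
        raise TaxonomyError("taxonomy config must be a mapping with a "
                            "'categories' key")
    name = str(doc.get("name", name))
    raw_cats = doc["categories"]
    if not isinstance(raw_cats, list) or not raw_cats:
        raise TaxonomyError("'categories' must be a non-empty list")

    tops: list[Category] = []
    subs: list[Category] = []
    for i, raw in enumerate(raw_cats):
        if not isinstance(raw, dict) or "id" not in raw:
            raise TaxonomyError(f"categories[{i}]: missing 'id'")
        cid = str(raw["id"])
        parent = raw.get("parent")
        cat = Category(
            id=cid,
            display_name=str(raw.get("name", cid)),
            level="sub" if parent else "top",
            parent_id=str(parent) if parent else None,
            lexicon=_parse_lexicon(raw.get("lexicon"), cid),
        )
        (subs if parent else tops).append(cat)

    top_ids = {c.id for c in tops}
    children: dict[str, list[Category]] = {c.id: [] for c in tops}
    for kid in subs:
        if kid.parent_id not in top_ids:
            raise TaxonomyError(
                f"child {kid.id!r} names undefined parent {kid.parent_id!r}"
            )
        children[kid.parent_id].append(kid)
    return Taxonomy(
        name=name,
        top_categories=tuple(tops),
        children={k: tuple(v) for k, v in children.items() if v},
    )


def dumps_taxonomy(t: Taxonomy) -> str:
    """Serialize a Taxonomy back to YAML; round-trips to an equal object."""
    cats = []
    for cat in t.all_categories():
        entry: dict[str, object] = {"id": cat.id, "name": cat.display_name}
        if cat.parent_id:
            entry["parent"] = cat.parent_id
        if cat.lexicon:
            entry["lexicon"] = [
                {"term": e.term, "kind": e.kind} for e in cat.lexicon
            ]
        cats.append(entry)
    return yaml.safe_dump(
        {"name": t.name, "categories": cats}, sort_keys=False, allow_unicode=True
    )


def load_default_taxonomy() -> Taxonomy:
    """The shipped six-category sleep-medicine comorbidity taxonomy
    (6 top-level categories, 29 subtypes, d = 35)."""
    text = (
        importlib.resources.files("comorbex.data")
        .joinpath("default_taxonomy.yaml")
        .read_text(encoding="utf-8")
    )
    return load_taxonomy(text, name="sleep_comorbidities_v1")
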