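"""Prefix registry and predicate schema for the AOP knowledge graph.

Every IRI the converter emits is owned here: the prefix→namespace registry
(metadata vocabularies, domain ontologies, identifiers.org compact-identifier
namespaces) and, per entity kind, the ordered table of predicates with their
object kinds and cardinalities. Both are loaded from the declarative data
file ``data/vocabulary.yaml`` so the schema can be extended without touching
emission code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

import yaml
from rdflib import URIRef

__all__ = [
    "Curie",
    "SchemaRow",
    "VocabRegistry",
    "load_registry",
    "UnknownPrefixError",
]

_CURIE_RE = re.compile(r"^([A-Za-z][\w.]*):(\S+)$")


class UnknownPrefixError(KeyError):
    """Raised when a CURIE prefix is not present in the registry."""

    def __init__(self, prefix: str):
        super().__init__(prefix)
        self.prefix = prefix

    def __str__(self) -> str:  # pragma: no cover - message formatting
        return f"unknown vocabulary prefix: {self.prefix!r}"


@dataclass(frozen=True, order=True)
class Curie:
    """A compact identifier ``prefix:local`` resolvable against the registry."""

    prefix: str
    local: str

    @classmethod
    def parse(cls, text: str) -> "Curie":
        m = _CURIE_RE.match(text)
        if not m:
            raise ValueError(f"not a CURIE: {text!r}")
        return cls(m.group(1), m.group(2))

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local}"


@dataclass(frozen=True)
class SchemaRow:
    """One predicate row of an entity's emission table."""

    predicate: Curie
    object_kind: str  # iri_ref | literal | typed_literal | url | iri_or_literal
    cardinality: str  # one | optional | many
    field: str | None = None
    fixed: tuple[Curie, ...] = ()
    datatype: Curie | None = None
    link: str | None = None  # entity kind the object IRI points at (internal link)
    gene_graph: bool = False  # row emitted into the gene graph, not the main graph


@dataclass
class VocabRegistry:
    """Prefix→namespace table plus the per-entity predicate schema."""

    prefixes: dict[str, str]          # prefix -> absolute base IRI
    categories: dict[str, str]        # prefix -> metadata | domain | identifier
    schemas: dict[str, tuple[SchemaRow, ...]]
    chemical_db_types: dict[str, Curie]
    gene_db_types: dict[str, Curie]
    term_types: dict[str, Curie]
    _order: dict[str, int] = field(default_factory=dict, repr=False)

    # -- CURIE resolution ---------------------------------------------------

    def resolve(self, curie: Curie | str) -> str:
        """Expand a CURIE to its absolute IRI (identifiers.org URL for
        identifier-category prefixes)."""
        if isinstance(curie, str):
            curie = Curie.parse(curie)
        try:
            base = self.prefixes[curie.prefix]
        except KeyError:
            raise UnknownPrefixError(curie.prefix) from None
        return base + curie.local

    def uri(self, curie: Curie | str) -> URIRef:
        return URIRef(self.resolve(curie))

    def compact(self, iri: str) -> Curie | None:
        """Inverse of :meth:`resolve`: longest-base match, or None."""
        best: tuple[int, str, str] | None = None
        for prefix, base in self.prefixes.items():
            if iri.startswith(base) and (best is None or len(base) > best[0]):
                best = (len(base), prefix, iri[len(base):])
        if best is None:
            return None
        return Curie(best[1], best[2])

    def namespace_of(self, iri: str) -> str | None:
        """Registry prefix owning *iri*, or None if unregistered."""
        c = self.compact(iri)
        return c.prefix if c is not None else None

    # -- schema access ------------------------------------------------------

    def schema_for(self, entity_kind: str) -> tuple[SchemaRow, ...]:
        """The ordered predicate table for one entity kind."""
        try:
            return self.schemas[entity_kind]
        except KeyError:
            known = ", ".join(sorted(self.schemas))
            raise KeyError(
                f"unknown entity kind {entity_kind!r} (known: {known})"
            ) from None

    def predicate_order(self, predicate_iri: str) -> int:
        """Global serialization rank of a predicate (schema order; unknown
        predicates sort after all schema predicates)."""
        return self._order.get(predicate_iri, len(self._order) + 1)

    def internal_link_predicates(self) -> set[str]:
        """IRIs of predicates whose objects link to other subjects in the
        graph (the asterisked rows of the schema tables)."""
        out: set[str] = set()
        for rows in self.schemas.values():
            for row in rows:
                if row.link is not None or row.gene_graph:
                    out.add(self.resolve(row.predicate))
        out.add(self.resolve("skos:exactMatch"))
        return out

    def iter_prefixes(self, category: str | None = None) -> Iterator[tuple[str, str]]:
        for prefix, base in self.prefixes.items():
            if category is None or self.categories[prefix] == category:
                yield prefix, base

    def ontology_prefixes(self) -> set[str]:
        """Prefixes of ontologies/vocabularies (everything except the
        identifiers.org identifier namespaces)."""
        return {p for p, c in self.categories.items() if c != "identifier"}


def _parse_row(raw: dict) -> SchemaRow:
    fixed = raw.get("fixed") or ()
    if isinstance(fixed, str):
        fixed = (fixed,)
    return SchemaRow(
        predicate=Curie.parse(raw["predicate"]),
        object_kind=raw["object_kind"],
        cardinality=raw["cardinality"],
        field=raw.get("field"),
        fixed=tuple(Curie.parse(f) for f in fixed),
        datatype=Curie.parse(raw["datatype"]) if raw.get("datatype") else None,
        link=raw.get("link"),
        gene_graph=bool(raw.get("gene_graph", False)),
    )


def load_registry(path: str | None = None) -> VocabRegistry:
    """Load the registry/schema, from *path* or the bundled data file."""
    if path is None:
        text = resources.files("aoprdf.data").joinpath("vocabulary.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)

    prefixes: dict[str, str] = {}
    categories: dict[str, str] = {}
    for entry in raw["prefixes"]:
        p = entry["prefix"]
        if p in prefixes:
            raise ValueError(f"duplicate prefix in registry: {p}")
        base = entry["base"]
        if "://" not in base:
            raise ValueError(f"base IRI not absolute for prefix {p}: {base}")
        prefixes[p] = base
        categories[p] = entry["category"]

    schemas = {
        kind: tuple(_parse_row(r) for r in rows)
        for kind, rows in raw["schemas"].items()
    }
    reg = VocabRegistry(
        prefixes=prefixes,
        categories=categories,
        schemas=schemas,
        chemical_db_types={k: Curie.parse(v) for k, v in raw["chemical_db_types"].items()},
        gene_db_types={k: Curie.parse(v) for k, v in raw["gene_db_types"].items()},
        term_types={k: Curie.parse(v) for k, v in raw["term_types"].items()},
    )
    order: dict[str, int] = {}
    rank = 0
    for rows in schemas.values():
        for row in rows:
            iri = reg.resolve(row.predicate)
            if iri not in order:
                order[iri] = rank
                rank += 1
    # rdf:type always serializes first
    order[reg.resolve("rdf:type")] = -1
    reg._order = order
    return reg
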