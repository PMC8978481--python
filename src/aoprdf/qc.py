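"""Validation and statistics over the emitted Turtle graphs.

Validation re-implements the two error classes an external Turtle validator
reports: syntax errors (via the RDF parser) and XSD datatype errors (typed
literals whose lexical form does not belong to the declared datatype's value
space). It additionally checks internal-link closure: objects of linking
predicates must appear as typed subjects somewhere in the loaded graphs.

Statistics are computed with SPARQL queries shipped in the query catalog
(``queries/``), covering the totals (unique triples / subjects / predicates /
objects), subjects per type, predicate frequency, ontology-namespace usage
(reported both per term and per namespace) and link-out counts per database.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dc_field
from datetime import date, datetime
from importlib import resources
from pathlib import Path

from rdflib import Graph, Literal, URIRef

from .vocab import VocabRegistry, load_registry

__all__ = [
    "ValidationReport",
    "StatsReport",
    "QueryEntry",
    "validate_files",
    "compute_stats",
    "query_catalog",
]


# ---------------------------------------------------------------------------
# validation

_XSD = "http://www.w3.org/2001/XMLSchema#"
_DATETIME_RE = re.compile(
    r"^\d{4}-\d{2}-\d{2}T\d{2}:\d{2}:\d{2}(\.\d+)?([+-]\d{2}:\d{2}|Z)?$"
)


@dataclass
class ValidationReport:
    syntax_ok: bool = True
    syntax_errors: list[str] = dc_field(default_factory=list)
    datatype_errors: list[tuple[str, str]] = dc_field(default_factory=list)
    dangling_links: list[str] = dc_field(default_factory=list)
    files: list[str] = dc_field(default_factory=list)
    triples: int = 0

    @property
    def ok(self) -> bool:
        return self.syntax_ok and not self.datatype_errors and not self.dangling_links

    def summary(self) -> dict:
        return {
            "files": self.files,
            "syntax_ok": self.syntax_ok,
            "syntax_errors": self.syntax_errors,
            "datatype_errors": [list(e) for e in self.datatype_errors],
            "dangling_links": self.dangling_links,
            "triples": self.triples,
            "ok": self.ok,
        }

    def text(self) -> str:
        lines = [f"validated {len(self.files)} file(s), {self.triples} triples"]
        lines.append(f"syntax: {'ok' if self.syntax_ok else 'FAILED'}")
        for e in self.syntax_errors:
            lines.append(f"  syntax error: {e}")
        lines.append(f"datatype errors: {len(self.datatype_errors)}")
        for t, msg in self.datatype_errors:
            lines.append(f"  {t}: {msg}")
        lines.append(f"dangling links: {len(self.dangling_links)}")
        for iri in self.dangling_links:
            lines.append(f"  {iri}")
        return "\n".join(lines)


def _check_datatype(lit: Literal) -> str | None:
    dt = str(lit.datatype) if lit.datatype else None
    lex = str(lit)
    if dt is None:
        return None
    if dt == _XSD + "dateTime":
        if not _DATETIME_RE.match(lex):
            return f"invalid xsd:dateTime lexical form {lex!r}"
        try:
            datetime.fromisoformat(lex.replace("Z", "+00:00"))
        except ValueError:
            return f"invalid xsd:dateTime value {lex!r}"
    elif dt == _XSD + "date":
        try:
            date.fromisoformat(lex)
        except ValueError:
            return f"invalid xsd:date value {lex!r}"
    elif dt in (_XSD + "integer", _XSD + "int", _XSD + "long"):
        if not re.match(r"^[+-]?\d+$", lex):
            return f"invalid xsd:integer value {lex!r}"
    elif dt in (_XSD + "decimal", _XSD + "double", _XSD + "float"):
        try:
            float(lex)
        except ValueError:
            return f"invalid {dt.rsplit('#')[-1]} value {lex!r}"
    elif dt == _XSD + "boolean":
        if lex not in ("true", "false", "0", "1"):
            return f"invalid xsd:boolean value {lex!r}"
    return None


def validate_files(
    paths: list[str | Path],
    registry: VocabRegistry | None = None,
) -> ValidationReport:
    """Validate Turtle files: syntax, XSD datatypes, internal-link closure.

    A syntax failure short-circuits the downstream checks (there is no graph
    to check). All issues are reported, none raise.
    """
    reg = registry or load_registry()
    report = ValidationReport()
    union = Graph()
    for path in paths:
        report.files.append(str(path))
        try:
            union.parse(str(path), format="turtle")
        except Exception as exc:  # rdflib raises several parse error types
            report.syntax_ok = False
            report.syntax_errors.append(f"{path}: {exc}")
    if not report.syntax_ok:
        return report

    report.triples = len(union)
    for s, p, o in union:
        if isinstance(o, Literal):
            msg = _check_datatype(o)
            if msg:
                report.datatype_errors.append(
                    (f"{s.n3()} {p.n3()} {o.n3()}", msg)
                )
    link_preds = {URIRef(i) for i in reg.internal_link_predicates()}
    typed_subjects = {s for s in union.subjects(URIRef(reg.resolve("rdf:type")), None)}
    dangling = set()
    for s, p, o in union:
        if p in link_preds and isinstance(o, URIRef) and o not in typed_subjects:
            dangling.add(str(o))
    report.dangling_links = sorted(dangling)
    report.datatype_errors.sort()
    return report


# ---------------------------------------------------------------------------
# statistics

@dataclass
class StatsReport:
    totals: dict[str, int] = dc_field(default_factory=dict)
    subject_type_counts: dict[str, int] = dc_field(default_factory=dict)
    predicate_frequency: dict[str, int] = dc_field(default_factory=dict)
    namespace_frequency: dict[str, int] = dc_field(default_factory=dict)
    ontology_namespaces: list[str] = dc_field(default_factory=list)
    linkout_counts: dict[str, int] = dc_field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "totals": self.totals,
            "subject_type_counts": self.subject_type_counts,
            "predicate_frequency": self.predicate_frequency,
            "namespace_frequency": self.namespace_frequency,
            "ontology_namespaces": self.ontology_namespaces,
            "linkout_counts": self.linkout_counts,
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)

    def text(self) -> str:
        t = self.totals
        lines = [
            f"triples: {t.get('triples', 0)}",
            f"unique subjects: {t.get('subjects', 0)}",
            f"unique predicates: {t.get('predicates', 0)}",
            f"unique objects: {t.get('objects', 0)}",
            f"ontology namespaces used: {len(self.ontology_namespaces)} "
            f"({', '.join(self.ontology_namespaces)})",
            "link-outs per database:",
        ]
        for db in sorted(self.linkout_counts):
            lines.append(f"  {db}: {self.linkout_counts[db]}")
        return "\n".join(lines)


def _union(graphs) -> Graph:
    union = Graph()
    for g in graphs:
        if isinstance(g, (str, Path)):
            union.parse(str(g), format="turtle")
        else:
            for t in g:
                union.add(t)
    return union


def compute_stats(
    graphs: list[Graph | str | Path] | Graph,
    registry: VocabRegistry | None = None,
) -> StatsReport:
    """Deterministic statistics over one or more graphs (or Turtle paths),
    computed with the catalog's SPARQL queries."""
    reg = registry or load_registry()
    if isinstance(graphs, Graph):
        graphs = [graphs]
    union = _union(graphs)
    catalog = {q.name: q for q in query_catalog()}
    report = StatsReport()

    row = next(iter(union.query(catalog["count_totals"].text)))
    report.totals = {
        "triples": int(row.triples),
        "subjects": int(row.subjects),
        "predicates": int(row.predicates),
        "objects": int(row.objects),
    }
    for r in union.query(catalog["subject_types"].text):
        report.subject_type_counts[str(r.type)] = int(r.n)
    for r in union.query(catalog["predicate_frequency"].text):
        report.predicate_frequency[str(r.p)] = int(r.n)

    db_of_type = {
        reg.resolve(c): db
        for db, c in {**reg.chemical_db_types, **reg.gene_db_types}.items()
    }
    for r in union.query(catalog["linkouts_by_type"].text):
        db = db_of_type.get(str(r.type))
        if db is not None:
            report.linkout_counts[db] = report.linkout_counts.get(db, 0) + int(r.n)

    # ontology usage, both granularities: per-term (predicate_frequency above)
    # and per-namespace over every IRI position
    ontology = reg.ontology_prefixes()
    ns_counts: dict[str, int] = {}
    for s, p, o in union:
        for term in (s, p, o):
            if isinstance(term, URIRef):
                ns = reg.namespace_of(str(term))
                if ns in ontology:
                    ns_counts[ns] = ns_counts.get(ns, 0) + 1
    report.namespace_frequency = dict(sorted(ns_counts.items()))
    report.ontology_namespaces = sorted(ns_counts)
    return report


# ---------------------------------------------------------------------------
# query catalog

@dataclass(frozen=True)
class QueryEntry:
    name: str
    text: str
    category: str  # statistics | example | federated
    network_required: bool = False


def query_catalog() -> list[QueryEntry]:
    """The bundled SPARQL queries (statistics, worked examples, and the
    federated WikiPathways template, which needs network access and is
    shipped untested against the live endpoint)."""
    entries = []
    qdir = resources.files("aoprdf.queries")
    for item in sorted(qdir.iterdir(), key=lambda p: p.name):
        if not item.name.endswith(".rq"):
            continue
        text = item.read_text()
        meta = {}
        for line in text.splitlines():
            if not line.startswith("#"):
                break
            m = re.match(r"#\s*([\w-]+):\s*(.+)", line)
            if m:
                meta[m.group(1)] = m.group(2).strip()
        entries.append(
            QueryEntry(
                name=meta.get("name", item.name[:-3]),
                text=text,
                category=meta.get("category", "example"),
                network_required=meta.get("network-required", "").startswith("yes"),
            )
        )
    return entries
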