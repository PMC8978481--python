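"""Emission of the knowledge graph: model → RDF triples → Turtle.

Three graphs are produced, mirroring the published file layout:

* the **main graph** (``AOP-Wiki.ttl``): every wiki entity (AOPs, key
  events, relationships, stressors, chemicals, annotated terms) described
  with the per-entity predicate tables of the vocabulary registry, plus
  chemical cross-references and PRotein-Ontology-derived gene/protein links;
* the **gene graph** (``AOP-Wiki-genes.ttl``): text-mapped HGNC identifiers
  on KEs/KERs and their cross-references;
* the **VoID graph** (``AOP-Wiki-void.ttl``): dataset metadata (title,
  license, provenance, triple and link-out counts).

Triples live in :class:`rdflib.Graph`; Turtle output goes through a small
canonical writer (subjects sorted, predicates in schema order, objects
sorted) so that two runs over the same input are byte-identical and diffs
are meaningful. The writer's output is plain Turtle 1.1 and is re-read with
rdflib in the validation step.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from rdflib import Graph, Literal, URIRef

from .model import (
    AopEntry,
    ChemicalEntry,
    KerEntry,
    KeyEventEntry,
    KnowledgeModel,
    StressorEntry,
    TermEntry,
)
from .vocab import Curie, VocabRegistry
from .xrefs import XrefRecord

logger = logging.getLogger(__name__)

__all__ = [
    "emit_aop",
    "emit_ke",
    "emit_ker",
    "emit_stressor",
    "emit_chemical",
    "emit_term",
    "build_main_graph",
    "build_gene_graph",
    "build_void_graph",
    "VoidConfig",
    "serialize_turtle",
    "serialize_ntriples",
    "turtle_text",
]

SOURCE_LITERAL = "AOPWiki"

Triple = tuple[URIRef, URIRef, "URIRef | Literal"]


# ---------------------------------------------------------------------------
# subject IRIs


def aop_iri(reg: VocabRegistry, aop_id: int) -> URIRef:
    return reg.uri(Curie("aop", str(aop_id)))


def ke_iri(reg: VocabRegistry, ke_id: int) -> URIRef:
    return reg.uri(Curie("aop.events", str(ke_id)))


def ker_iri(reg: VocabRegistry, ker_id: int) -> URIRef:
    return reg.uri(Curie("aop.relationships", str(ker_id)))


def stressor_iri(reg: VocabRegistry, s_id: int) -> URIRef:
    return reg.uri(Curie("aop.stressor", str(s_id)))


def chemical_iri(reg: VocabRegistry, cas: str) -> URIRef:
    return reg.uri(Curie("cas", cas))


def gene_iri(reg: VocabRegistry, hgnc_id: str) -> URIRef:
    return reg.uri(Curie("hgnc", hgnc_id))


def xref_iri(reg: VocabRegistry, xref: XrefRecord) -> URIRef:
    return reg.uri(Curie(xref.target_db, xref.target_id))


def term_node(reg: VocabRegistry, key: str) -> URIRef | Literal:
    """Ontology CURIEs become IRIs; free-text term keys stay plain literals
    (the wiki's free-text taxonomy and action tokens, e.g. "WCS_9606")."""
    if ":" in key:
        prefix, local = key.split(":", 1)
        p = prefix.lower()
        if p in reg.prefixes:
            return reg.uri(Curie(p, local))
        # free-text tokens that merely look like CURIEs (e.g. "WIKI:2")
        logger.debug("term key %r has no registered prefix; emitted as literal", key)
    return Literal(key)


# ---------------------------------------------------------------------------
# generic row-driven emission


def _as_list(value) -> list:
    if value is None:
        return []
    if isinstance(value, (list, tuple, set)):
        return list(value)
    return [value]


def _emit_rows(
    subject: URIRef,
    kind: str,
    entity,
    reg: VocabRegistry,
    special: dict[str, list],
) -> set[Triple]:
    """Walk one entity's schema table and build its triples.

    *special* supplies objects for rows that do not read a model field
    directly (identifier, label, page, source, isPartOf, exactMatch, ...),
    keyed by the predicate CURIE string. Rows flagged ``gene_graph`` are
    skipped here; the gene-graph builder owns them.
    """
    triples: set[Triple] = set()
    rdf_type = reg.uri("rdf:type")
    for row in reg.schema_for(kind):
        pred_key = str(row.predicate)
        if row.gene_graph and pred_key not in special:
            continue
        predicate = reg.uri(row.predicate)
        objects: list = []
        if row.fixed:
            objects = [reg.uri(c) for c in row.fixed]
        elif pred_key in special:
            objects = _as_list(special[pred_key])
        elif row.field is not None:
            raw = _as_list(getattr(entity, row.field, None))
            for value in raw:
                objects.append(_convert(value, row, reg))
        for obj in objects:
            if obj is None:
                continue
            triples.add((subject, predicate, obj))
            if predicate == rdf_type and not isinstance(obj, URIRef):
                raise TypeError("rdf:type object must be an IRI")
    return triples


def _convert(value, row, reg: VocabRegistry):
    if value is None:
        return None
    if row.object_kind == "literal":
        return Literal(str(value))
    if row.object_kind == "typed_literal":
        lex = value.isoformat() if hasattr(value, "isoformat") else str(value)
        return Literal(lex, datatype=reg.uri(row.datatype))
    if row.object_kind in ("iri_ref", "iri_or_literal", "url"):
        if row.link == "ke":
            return ke_iri(reg, int(value))
        if row.link == "ker":
            return ker_iri(reg, int(value))
        if row.link == "stressor":
            return stressor_iri(reg, int(value))
        if row.link == "aop":
            return aop_iri(reg, int(value))
        if row.link == "chemical":
            return chemical_iri(reg, str(value))
        if row.link in ("inchikey", "comptox"):
            return reg.uri(Curie(row.link, str(value)))
        if row.link == "term":
            node = term_node(reg, str(value))
            if isinstance(node, Literal) and row.object_kind == "iri_ref":
                logger.warning("free-text value %r for IRI-only predicate %s",
                               value, row.predicate)
            return node
        return URIRef(str(value))
    raise ValueError(f"unknown object kind {row.object_kind!r}")


# ---------------------------------------------------------------------------
# per-entity emitters


def emit_aop(aop: AopEntry, model: KnowledgeModel, reg: VocabRegistry) -> set[Triple]:
    subject = aop_iri(reg, aop.id)
    special = {
        "dc:identifier": [subject],
        "rdfs:label": [Literal(f"AOP {aop.id}")],
        "foaf:page": [URIRef(reg.resolve(Curie("aop", str(aop.id))))],
        "dc:source": [Literal(SOURCE_LITERAL)],
    }
    return _emit_rows(subject, "aop", aop, reg, special)


def emit_ke(ke: KeyEventEntry, model: KnowledgeModel, reg: VocabRegistry) -> set[Triple]:
    subject = ke_iri(reg, ke.id)
    parents = sorted(a.id for a in model.aops.values() if ke.id in a.ke_ids)
    special = {
        "dc:identifier": [subject],
        "rdfs:label": [Literal(f"KE {ke.id}")],
        "foaf:page": [URIRef(reg.resolve(Curie("aop.events", str(ke.id))))],
        "dc:source": [Literal(SOURCE_LITERAL)],
        "dcterms:isPartOf": [aop_iri(reg, a) for a in parents],
    }
    return _emit_rows(subject, "ke", ke, reg, special)


def emit_ker(ker: KerEntry, model: KnowledgeModel, reg: VocabRegistry) -> set[Triple]:
    subject = ker_iri(reg, ker.id)
    parents = sorted(a.id for a in model.aops.values() if ker.id in a.ker_ids)
    special = {
        "dc:identifier": [subject],
        "rdfs:label": [Literal(f"KER {ker.id}")],
        "foaf:page": [URIRef(reg.resolve(Curie("aop.relationships", str(ker.id))))],
        "dcterms:isPartOf": [aop_iri(reg, a) for a in parents],
    }
    return _emit_rows(subject, "ker", ker, reg, special)


def emit_stressor(
    s: StressorEntry, model: KnowledgeModel, reg: VocabRegistry
) -> set[Triple]:
    subject = stressor_iri(reg, s.id)
    parent_aops = sorted(a.id for a in model.aops.values() if s.id in a.stressor_ids)
    parent_kes = sorted(k.id for k in model.kes.values() if s.id in k.stressor_ids)
    special = {
        "dc:identifier": [subject],
        "rdfs:label": [Literal(f"Stressor {s.id}")],
        "foaf:page": [URIRef(reg.resolve(Curie("aop.stressor", str(s.id))))],
        # KEs first, then AOPs, matching the published object ordering
        "dcterms:isPartOf": [ke_iri(reg, k) for k in parent_kes]
        + [aop_iri(reg, a) for a in parent_aops],
    }
    return _emit_rows(subject, "stressor", s, reg, special)


def emit_chemical(
    c: ChemicalEntry,
    xrefs: set[XrefRecord],
    model: KnowledgeModel,
    reg: VocabRegistry,
) -> set[Triple]:
    """Chemical node (subject = its CAS IRI) plus the type annotations of
    every identifier node it points at (the chemical-database type table)."""
    subject = chemical_iri(reg, c.cas)
    rdf_type = reg.uri("rdf:type")
    parents = sorted(s.id for s in model.stressors.values() if c.cas in s.chemical_cas)
    match_iris = sorted(xref_iri(reg, x) for x in xrefs)
    special = {
        "dc:identifier": [subject],
        "skos:exactMatch": match_iris,
        "dcterms:isPartOf": [stressor_iri(reg, s) for s in parents],
    }
    triples = _emit_rows(subject, "chemical", c, reg, special)
    # identifier-node typing: the chemical's own InChIKey/CompTox nodes and
    # every exactMatch target carry the database type of Table "chemical_db_types"
    for field_name in ("inchikey", "comptox"):
        value = getattr(c, field_name)
        if value is not None:
            node = reg.uri(Curie(field_name, value))
            triples.add((node, rdf_type, reg.uri(reg.chemical_db_types[field_name])))
    for x in xrefs:
        triples.add((xref_iri(reg, x), rdf_type,
                     reg.uri(reg.chemical_db_types[x.target_db])))
    return triples


def emit_term(
    term: TermEntry,
    reg: VocabRegistry,
    pr_xrefs: set[XrefRecord] | None = None,
) -> set[Triple]:
    """Term node for an ontology-annotated term. Free-text terms have no IRI
    and therefore no subject node (they appear as literals on the entities
    that use them)."""
    node = term_node(reg, term.key)
    if isinstance(node, Literal):
        return set()
    rdf_type = reg.uri("rdf:type")
    special = {
        "rdf:type": [reg.uri(reg.term_types[term.kind])],
        "dc:identifier": [node],
        "skos:exactMatch": sorted(xref_iri(reg, x) for x in (pr_xrefs or set())),
        "dc:source": [Literal(SOURCE_LITERAL)],
    }
    triples = _emit_rows(node, "term", term, reg, special)
    for x in pr_xrefs or set():
        triples.add((xref_iri(reg, x), rdf_type, reg.uri(reg.gene_db_types[x.target_db])))
    return triples


# ---------------------------------------------------------------------------
# graph builders


def build_main_graph(
    model: KnowledgeModel,
    reg: VocabRegistry,
    chemical_xrefs: dict[str, set[XrefRecord]] | None = None,
    pr_xrefs: dict[str, set[XrefRecord]] | None = None,
) -> Graph:
    """The central graph: all wiki entities plus chemical cross-references
    and PR-derived gene/protein links.

    *chemical_xrefs* maps CAS → xref set; *pr_xrefs* maps a PR term key
    (e.g. ``PR:000008478``) → xref set.
    """
    chemical_xrefs = chemical_xrefs or {}
    pr_xrefs = pr_xrefs or {}
    g = _new_graph(reg)
    for aop in model.aops.values():
        _add(g, emit_aop(aop, model, reg))
    for ke in model.kes.values():
        _add(g, emit_ke(ke, model, reg))
    for ker in model.kers.values():
        _add(g, emit_ker(ker, model, reg))
    for s in model.stressors.values():
        _add(g, emit_stressor(s, model, reg))
    for c in model.chemicals.values():
        _add(g, emit_chemical(c, chemical_xrefs.get(c.cas, set()), model, reg))
    for term in model.terms.values():
        _add(g, emit_term(term, reg, pr_xrefs.get(term.key)))
    return g


def build_gene_graph(
    entity_matches: dict[tuple[str, int], set[str]],
    gene_xrefs: dict[str, set[XrefRecord]],
    reg: VocabRegistry,
) -> Graph:
    """The text-mapped gene graph.

    *entity_matches* maps ("ke"|"ker", entity id) → set of HGNC ids matched
    anywhere in that entity's scanned fields; *gene_xrefs* maps HGNC id →
    cross-references. Every gene subject is typed as an HGNC identifier and
    linked to its typed cross-references with skos:exactMatch.
    """
    g = _new_graph(reg)
    rdf_type = reg.uri("rdf:type")
    link = reg.uri("edam:data_1025")
    exact = reg.uri("skos:exactMatch")
    seen_genes: set[str] = set()
    for (kind, entity_id), genes in sorted(entity_matches.items()):
        subject = ke_iri(reg, entity_id) if kind == "ke" else ker_iri(reg, entity_id)
        for hgnc_id in sorted(genes):
            g.add((subject, link, gene_iri(reg, hgnc_id)))
            seen_genes.add(hgnc_id)
    for hgnc_id in sorted(seen_genes):
        subject = gene_iri(reg, hgnc_id)
        g.add((subject, rdf_type, reg.uri(reg.gene_db_types["hgnc"])))
        for x in sorted(gene_xrefs.get(hgnc_id, set())):
            target = xref_iri(reg, x)
            g.add((subject, exact, target))
            g.add((target, rdf_type, reg.uri(reg.gene_db_types[x.target_db])))
    return g


@dataclass
class VoidConfig:
    """Run metadata carried into the VoID description."""

    base_iri: str = "https://example.org/aop-rdf/"
    license: str = "https://creativecommons.org/licenses/by/4.0/"
    creator: str = "aoprdf"
    created: str | None = None       # ISO date; defaults to the snapshot date
    snapshot_date: str | None = None
    main_name: str = "AOP-Wiki.ttl"
    genes_name: str = "AOP-Wiki-genes.ttl"
    homepage: str | None = None
    titles: dict[str, str] = dc_field(default_factory=lambda: {
        "main": "AOP-Wiki RDF: pathways, key events, relationships, "
                "stressors, chemicals and term annotations",
        "genes": "AOP-Wiki RDF gene annex: text-mapped HGNC identifiers "
                 "and their cross-references",
    })


def build_void_graph(
    main_graph: Graph,
    gene_graph: Graph,
    reg: VocabRegistry,
    config: VoidConfig | None = None,
) -> Graph:
    """VoID/DCAT metadata describing the two data graphs: titles, license,
    provenance dates, triple/subject/property counts and per-database
    link-out linksets. Counts are measured from the graphs themselves."""
    config = config or VoidConfig()
    g = _new_graph(reg)
    created = config.created or config.snapshot_date or "1970-01-01"
    xsd_date = reg.uri("xsd:date")
    xsd_int = reg.uri("xsd:integer")
    exact = reg.uri("skos:exactMatch")
    rdf_type = reg.uri("rdf:type")
    db_of_type = {
        reg.resolve(c): db
        for db, c in {**reg.chemical_db_types, **reg.gene_db_types}.items()
    }
    for tag, graph in (("main", main_graph), ("genes", gene_graph)):
        name = config.main_name if tag == "main" else config.genes_name
        d = URIRef(config.base_iri + name)
        g.add((d, rdf_type, reg.uri("void:Dataset")))
        g.add((d, rdf_type, reg.uri("dcat:Dataset")))
        g.add((d, reg.uri("dcterms:title"), Literal(config.titles[tag])))
        g.add((d, reg.uri("dcterms:license"), URIRef(config.license)))
        g.add((d, reg.uri("dcterms:creator"), Literal(config.creator)))
        g.add((d, reg.uri("dcterms:created"), Literal(created, datatype=xsd_date)))
        g.add((d, reg.uri("pav:createdOn"), Literal(created, datatype=xsd_date)))
        if config.snapshot_date:
            g.add((d, reg.uri("dc:source"),
                   Literal(f"AOP-Wiki XML snapshot {config.snapshot_date}")))
        g.add((d, reg.uri("void:dataDump"), d))
        if config.homepage:
            g.add((d, reg.uri("foaf:page"), URIRef(config.homepage)))
        g.add((d, reg.uri("void:triples"), Literal(str(len(graph)), datatype=xsd_int)))
        subjects = {s for s, _, _ in graph}
        props = {p for _, p, _ in graph}
        objects = {o for _, _, o in graph}
        g.add((d, reg.uri("void:distinctSubjects"),
               Literal(str(len(subjects)), datatype=xsd_int)))
        g.add((d, reg.uri("void:properties"),
               Literal(str(len(props)), datatype=xsd_int)))
        g.add((d, reg.uri("void:distinctObjects"),
               Literal(str(len(objects)), datatype=xsd_int)))
        # link-outs: exactMatch targets partitioned by database type
        counts: dict[str, int] = {}
        for _, _, o in graph.triples((None, exact, None)):
            for t in graph.objects(o, rdf_type):
                db = db_of_type.get(str(t))
                if db:
                    counts[db] = counts.get(db, 0) + 1
        for db in sorted(counts):
            ls = URIRef(f"{config.base_iri}{name}#links-{db}")
            g.add((ls, rdf_type, reg.uri("void:Linkset")))
            g.add((ls, reg.uri("void:subjectsTarget"), d))
            g.add((ls, reg.uri("void:linkPredicate"), exact))
            g.add((ls, reg.uri("dcterms:description"), Literal(db)))
            g.add((ls, reg.uri("void:triples"),
                   Literal(str(counts[db]), datatype=xsd_int)))
    return g


def _new_graph(reg: VocabRegistry) -> Graph:
    g = Graph()
    for prefix, base in reg.iter_prefixes():
        g.bind(prefix, base, replace=True)
    return g


def _add(g: Graph, triples: set[Triple]) -> None:
    for t in triples:
        g.add(t)


# ---------------------------------------------------------------------------
# canonical Turtle writer

_PN_LOCAL_RE = re.compile(r"^[A-Za-z0-9_](?:[A-Za-z0-9_.\-]*[A-Za-z0-9_\-])?$")
_ESCAPES = {"\\": "\\\\", '"': '\\"', "\n": "\\n", "\r": "\\r", "\t": "\\t"}


def _escape_literal(text: str) -> str:
    return "".join(_ESCAPES.get(ch, ch) for ch in text)


def _qname(iri: str, reg: VocabRegistry, used: set[str]) -> str:
    c = reg.compact(iri)
    if c is not None and _PN_LOCAL_RE.match(c.local):
        used.add(c.prefix)
        return f"{c.prefix}:{c.local}"
    return f"<{iri}>"


def _render_object(obj, reg: VocabRegistry, used: set[str]) -> str:
    if isinstance(obj, URIRef):
        return _qname(str(obj), reg, used)
    if isinstance(obj, Literal):
        body = f'"{_escape_literal(str(obj))}"'
        if obj.datatype:
            return body + "^^" + _qname(str(obj.datatype), reg, used)
        if obj.language:
            return body + "@" + obj.language
        return body
    raise TypeError(f"cannot serialize {obj!r}")


def turtle_text(graph: Graph, reg: VocabRegistry) -> str:
    """Canonical Turtle: subjects sorted by IRI, predicates in schema order
    (rdf:type first, rendered as ``a``), objects sorted lexically."""
    rdf_type = reg.resolve("rdf:type")
    by_subject: dict[str, dict[str, set]] = {}
    for s, p, o in graph:
        by_subject.setdefault(str(s), {}).setdefault(str(p), set()).add(o)

    used: set[str] = set()
    blocks: list[str] = []
    for s in sorted(by_subject):
        preds = by_subject[s]
        lines = []
        subject_txt = _qname(s, reg, used)
        ordered = sorted(preds, key=lambda p: (reg.predicate_order(p), p))
        for p in ordered:
            p_txt = "a" if p == rdf_type else _qname(p, reg, used)
            objs = sorted(_render_object(o, reg, used) for o in preds[p])
            lines.append(f"    {p_txt} {', '.join(objs)}")
        blocks.append(subject_txt + "\n" + " ;\n".join(lines) + " .")

    header = "".join(
        f"@prefix {prefix}: <{reg.prefixes[prefix]}> .\n"
        for prefix in sorted(used)
    )
    body = "\n\n".join(blocks)
    return header + ("\n" if blocks else "") + body + ("\n" if blocks else "")


def serialize_turtle(graph: Graph, path: str | Path, reg: VocabRegistry) -> Path:
    """Write canonical Turtle to *path* (UTF-8); returns the path."""
    path = Path(path)
    try:
        path.write_text(turtle_text(graph, reg), encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write Turtle file {path}: {exc}") from exc
    return path


def serialize_ntriples(graph: Graph, path: str | Path) -> Path:
    """Sorted N-Triples export (round-trip and diff tooling)."""
    path = Path(path)
    lines = sorted(
        f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in graph
    )
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return path
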