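# Methods

This note documents the model behind the conversion, the choices made where
the design was genuinely open, and what the bundled fixtures do and do not
demonstrate.

## Knowledge model

One XML dump is parsed into keyed collections of typed entries: AOPs, key
events (KEs), key event relationships (KERs), stressors, chemicals and the
pre-annotated ontology terms, the latter covering cell-terms, organ-terms,
taxonomy entries and the three KE-component kinds (biological process,
object, action). Structural invariants are enforced at parse time:

* entity ids are positive integers, unique within their collection;
  chemicals are keyed by CAS number (loose pattern `\d{2,7}-\d{2}-\d`);
  InChIKeys must match the 14–10–1 uppercase block form or are dropped;
* an AOP's MIE and AO lists must be subsets of its KE list — offending ids
  are dropped with a warning, since the downstream graph makes that subset
  relation a queryable commitment;
* a KER whose upstream equals its downstream KE is rejected (a self-loop
  has no meaning in a directed event chain); a KER referencing an unknown
  KE is kept and the reference recorded as *dangling* — live wiki content
  contains work in progress, so dangling references are warnings, never
  errors;
* timestamps are ISO-8601 without timezone, the wiki's own form; an entry
  whose creation postdates its modification is flagged but kept.

Nothing is lost silently: parsed + skipped-with-warning equals the entities
present in the document, and the parse report carries every warning and
dangling reference.

Real dumps may spell elements differently from the documented fixture
dialect (see `docs/xml_dialect.md`); a YAML *dialect mapping* renames
elements/attributes per field without code changes. Fidelity to any
particular quarterly dump can only be established against that dump itself.

## Vocabulary and predicate schema

All IRIs are owned by a declarative registry
(`src/aoprdf/data/vocabulary.yaml`) with three categories: standard metadata
vocabularies (dc, dcterms, rdfs, foaf, skos, pav, void, dcat, …), domain
ontologies (aopo, pato, cheminf, nci, mmo, ncbitaxon, go, edam plus the
annex term namespaces cl, uberon, mi, mp, mesh, hp, pco, nbo, vt, pr, fma),
and identifiers.org compact-identifier namespaces (aop, aop.events,
aop.relationships, aop.stressor, cas, inchikey, comptox and the external
chemical/gene databases). Identifier IRIs follow the
`https://identifiers.org/<prefix>/<id>` pattern so every emitted subject
resolves to its database page. Notable choices:

* the annex ontology list is reconstructed from the prose enumeration of
  pre-annotated term sources; base IRIs follow OBO PURL conventions (MeSH
  and FMA use their own PURL schemes). It is a reconstruction — an exact
  supplementary listing is not machine-readable here;
* ChEBI occurs both as a chemical cross-reference database and as a term
  namespace; a single `chebi` identifiers.org entry serves both so registry
  prefixes stay unique (consequence: ChEBI counts as an identifier
  namespace, not an ontology, in the namespace statistics);
* CompTox identifiers use the identifiers.org `comptox` namespace rather
  than dashboard URLs, for uniform resolvability.

Per entity kind, an ordered predicate table fixes predicate, object kind
(IRI / literal / typed literal / URL), cardinality and internal-link role.
The AOP table has exactly 26 predicate types; KE/KER/stressor/chemical/term
tables carry their own rows, including the 12-row chemical-database and
4-row gene-database type maps used to annotate identifier nodes. Emission
walks these tables, so the serialized predicate order equals table order and
the schema can be extended by editing data, not code.

## Gene text mapping

The dictionary is built from an HGNC-style gene table. Matching semantics:

* **Boundary-aware exact matching.** A form matches only when flanked by a
  separator (whitespace or `()[]{}.,;:/"'-`) or the string edge. This is
  equivalent to enumerating separator variants around every symbol, without
  the combinatorial dictionary blow-up, and it provably excludes
  partial-word hits (`sURODx` never matches `UROD`).
* **Case policy.** Approved and alias *symbols* match case-sensitively;
  full gene *names* and multi-word aliases match case-insensitively.
  Whether the original procedure was case-sensitive is not documented;
  case-sensitive symbols were chosen because symbol/abbreviation collisions
  are the method's acknowledged failure mode and case sensitivity removes a
  large class of them. The method remains deliberately permissive —
  exact dictionary matching, not named-entity recognition — so residual
  collisions with free-text abbreviations are expected on real data.
* **Collisions.** When two genes claim one surface form, the approved
  symbol beats a name beats an alias; remaining ties resolve to the lowest
  numeric HGNC id. Every resolution is logged and kept on the dictionary
  object for audit.
* **Tunables.** Minimum form length (default 2 characters, excluding
  single-letter forms) and an optional stop-list for known-ambiguous
  symbols (default empty, matching the permissive published behaviour).

Exactly five fields are scanned: KE description, the MIE/AO-specific KE
section, KER description, biological plausibility and empirical support.
The full match list (with character spans) is retained for audit; emission
deduplicates to one HGNC id per entity. The implementation (regex with
lookaround boundaries, lookahead so overlapping occurrences of a form are
all found) is tested for equality against an independent brute-force oracle
(every occurrence of every form via `str.find`, boundaries checked
explicitly) on hundreds of random ~10 kb texts and on
hypothesis-generated adversarial strings.

PRotein Ontology biological objects are mapped to UniProt/HGNC/NCBI Gene
through a promapping-style table; all relation values are treated as
mappable (the source file's relation semantics are not formally specified),
and HGNC targets carry gene symbols, matching the symbol-keyed `hgnc:` IRIs
in the graph.

## Identifier expansion

A `MapperBackend` contract (pure lookup; unknown source → empty set)
decouples the pipeline from any particular mapping service. The default is
an offline four-column static table; a BridgeDb-compatible HTTP backend
(`GET {base}/{organism}/xrefs/{systemCode}/{id}`, two-column response,
404 = no mapping, transport failures raised as retriable errors distinct
from "no mapping") is available but never exercised against the network in
tests — its client path is tested with recorded/mocked responses. Chemical
results are restricted to the nine covered chemical databases and gene
results to NCBI Gene/UniProt/Ensembl; out-of-scope rows are filtered and
logged. Only direct answers are used — no transitive mapping — and each CAS
number of a multi-chemical stressor is mapped independently.

## Emission and serialization

Each entity becomes one subject with its table-driven triples. Internal
links (the "asterisked" predicates: pathway→KE/KER/stressor, KER→KE,
stressor→chemical, term links, `skos:exactMatch`, gene links) always point
at IRIs that are themselves typed subjects — the *referential closure*
invariant checked by the validator and the test suite. Specific choices:

* literals are plain strings except `dcterms:created`/`modified`
  (`xsd:dateTime`) and the VoID counts (`xsd:integer`, `xsd:date`); no
  language tags;
* `foaf:page` objects are IRI resources, not literals;
* KE-component actions and taxa without ontology ids (free-text tokens such
  as `WIKI:2` or `WCS_9606`) are emitted as plain literals; terms with
  CURIEs become IRI nodes typed per the term-type table;
* chemicals are subjects at their CAS IRI, typed as both "chemical entity"
  and "CAS registry number" (`cheminf:000000` + `cheminf:000446`); their
  InChIKey/CompTox nodes and every `skos:exactMatch` target carry the
  database type annotation of the 12-row chemical map;
* graph split: all wiki content plus chemical and PR-derived identifiers go
  to the main file; text-mapped genes and their cross-references to the
  gene file; dataset metadata to the VoID file.

Turtle output goes through a canonical in-package writer (rdflib remains
the container, parser and SPARQL engine): subjects sorted by IRI,
predicates in schema order with `rdf:type` first, objects sorted lexically,
prefix header restricted to used prefixes. This makes re-runs byte-identical
and diffs meaningful; `serialize → parse → serialize` is a fixed point. The
VoID creation date defaults to the dump's snapshot date rather than
wall-clock time precisely to preserve byte-identical re-runs.

## Validation and statistics

Validation re-implements the two error classes of an external Turtle
validator — syntax (via the RDF parser) and XSD datatype errors (explicit
lexical checks for dateTime/date/integer/decimal/boolean) — plus the
internal-link closure check; a syntax failure short-circuits the rest.
Statistics run as SPARQL over the loaded graphs using the bundled query
catalog: totals (unique triples/subjects/predicates/objects), subjects per
type, predicate frequency, and link-outs partitioned by the database type
of `skos:exactMatch` targets. Ontology usage is reported at both
granularities (per term via predicate frequency, per namespace over all IRI
positions) since either reading is defensible. The catalog also ships
worked biological example queries and a federated WikiPathways template;
the template declares a `SERVICE` clause, requires network access, and is
bundled untested against the live endpoint.

## Synthetic fixtures — what they show and what they do not

The random generator plants gene symbols (from a bundled 50-symbol
mini-table of real human gene nomenclature) into lorem-style filler text at
recorded positions, adds decoy tokens (symbols embedded inside longer
alphanumeric words), builds consistent pathway/KE/KER/stressor/chemical
structures, and writes the companion HGNC/PR/xref tables together with a
truth object recorded *while planting* — so end-to-end tests assert exact
equality of matches, cross-references and counts, not statistical
agreement. Default shape: 3 pathways × 4 KEs, 4 stressors, 3 chemicals,
75 % of stressors chemical-bearing, 0–3 planted genes per scanned field,
decoy rate 0.3, 80 % database coverage per chemical — a deliberately small
but fully-featured wiki; identical seeds give byte-identical bundles.

The canonical fixture is a hand-written bundle mirroring well-known public
wiki records (AOP 38, KE 1502, KER 865, stressor 208, acetaminophen) with
one maximally populated pathway and one KE annotated across the annex
ontologies; its expected conversion triples are frozen in
`CANONICAL_EXEMPLARS`.

What passing these tests does *not* show: fidelity to any real quarterly
dump's element dialect, dictionary behaviour on natural prose (filler text
has none of the ambiguity of real toxicology writing — on real data the
permissive matcher will produce false positives), or the behaviour of live
mapping services. Full-scale outputs (hundreds of pathways, >100 k triples)
depend on external downloads and are outside the test scope; the fixtures
exercise every code path at desk scale in seconds.

## Known limitations

* The matcher assumes markup-free plain text; HTML stripping is upstream.
* Life-stage applicability is modelled as a single optional value per
  entity although the wiki can carry several; the first is kept.
* The HTTP backend trusts the service's datasource naming; unknown
  datasource labels are skipped with a log line.
* VoID link-out linksets describe targets by database token, not by a
  formal target-dataset description.
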