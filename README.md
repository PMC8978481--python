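# aoprdf

Convert AOP-Wiki-style XML dumps into an ontology-annotated RDF knowledge
graph (Turtle + VoID), enriched with gene, protein and chemical
cross-identifiers, with validation and SPARQL statistics tooling.

## Why

Adverse outcome pathways (AOPs) describe toxicological mechanisms as chains
of key events (KEs) — from a molecular initiating event (MIE) perturbed by a
chemical stressor to an adverse outcome (AO) — connected by key event
relationships (KERs). The main repository of AOPs, the AOP-Wiki, publishes
its content as XML dumps dominated by free text, which makes systematic,
cross-database querying hard. This package turns such a dump into Linked
Data: every entity gets a resolvable identifiers.org IRI, every property is
annotated with a term from a standard vocabulary or domain ontology (Dublin
Core, the AOP Ontology, PATO, CHEMINF, NCI Thesaurus, Gene Ontology, EDAM,
…), and the free text is mined for gene mentions so that pathways, key
events, chemicals, genes and proteins become joinable with external
resources through SPARQL — including federated queries against endpoints
such as WikiPathways.

It is a library first (`import aoprdf`, see `examples/`), with a thin
`aoprdf` command-line tool on top.

## The conversion in one paragraph

The XML dump is parsed into a typed knowledge model (AOPs, KEs, KERs,
stressors, chemicals and the pre-annotated ontology terms for cells, organs,
taxa and KE components). Three enrichment steps follow: (1) *dictionary text
matching* — a surface-form dictionary built from an HGNC gene table
(approved symbols case-sensitive; names and multi-word aliases
case-insensitive) is scanned over five free-text fields (KE description,
MIE/AO section, KER description, biological plausibility, empirical
support), with a match only counting when flanked by separator characters,
so `sURODx` never matches `UROD`; (2) *PRotein Ontology mapping* —
biological-object PR terms are mapped to UniProt/HGNC/NCBI Gene through a
promapping-style table; (3) *identifier expansion* — each chemical's CAS
number is mapped into nine chemical databases (ChEBI, ChemSpider, Wikidata,
ChEMBL, PubChem, DrugBank, KEGG, LIPID MAPS, HMDB) and each text-mapped gene
into NCBI Gene, UniProt and Ensembl through a pluggable backend (offline
static table by default; BridgeDb-compatible HTTP service optional). The
result is written as three deterministic Turtle files: `AOP-Wiki.ttl` (all
wiki content + chemical and PR-derived identifiers), `AOP-Wiki-genes.ttl`
(text-mapped genes and their cross-references) and `AOP-Wiki-void.ttl`
(VoID/DCAT dataset metadata with measured triple and link-out counts).

The entire predicate schema — 26 predicate types for an AOP subject, the KE,
KER, stressor and chemical tables, 12 chemical-database and 4 gene-database
type annotations, 6 term types — lives in one declarative data file
(`src/aoprdf/data/vocabulary.yaml`); emission code contains no hard-coded
vocabulary strings.

## Worked example

```bash
aoprdf fixture --canonical --outdir fx     # small example wiki + tables
aoprdf convert --xml fx/canonical.xml --hgnc fx/hgnc.tsv \
    --pr fx/promapping.tsv --xrefs fx/xrefs.tsv --outdir out
aoprdf validate out/*.ttl
aoprdf stats out/*.ttl
```

The convert step reports (stderr):

```
aops: 10
kes: 11
kers: 3
stressors: 8
chemicals: 2
text_mapped_genes: 4
triples_main: 429
triples_genes: 32
warnings: 0
```

and `aoprdf stats` prints, among other things:

```
triples: 559
unique subjects: 99
unique predicates: 58
ontology namespaces used: 28 (aopo, cheminf, cl, dc, dcat, dcterms, edam, ...)
link-outs per database:
  chebi: 2
  ...
```

Reading: the example wiki's 10 pathways, 11 key events and 3 relationships
become 559 unique triples; 4 gene symbols (UROD, HDAC9, MAA, PRDX2) were
text-mapped from KE/KER free text into the gene graph; the output draws on
28 distinct ontologies/vocabularies; link-outs count the typed
`skos:exactMatch` targets per external database. The same objects are
available programmatically — `examples/` contains one short script per
capability (conversion, text scanning, identifier mapping, validation and
statistics, SPARQL catalog).

## Scope notes

Conversion of a real quarterly dump requires the dump itself, a current HGNC
table, a promapping file and a mapping service — all external downloads; the
package ships a dialect-mapping mechanism (`--dialect`, YAML) so real dumps
with different element names can be adapted without code changes. Hosting a
SPARQL endpoint and executing the bundled federated query template against
live remote endpoints are out of scope.
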