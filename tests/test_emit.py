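"""Triple emission and canonical Turtle serialization."""

from rdflib import Graph, Literal, URIRef

from aoprdf import emit, pipeline
from aoprdf.emit import turtle_text
from aoprdf.model import AopEntry, KeyEventEntry, KnowledgeModel, StressorEntry


def u(reg, curie):
    return URIRef(reg.resolve(curie))


def test_minimal_aop_gets_only_the_mandatory_triples(reg):
    model = KnowledgeModel()
    aop = AopEntry(id=7, title="bare pathway")
    model.aops[7] = aop
    triples = emit.emit_aop(aop, model, reg)
    preds = {str(p) for _, p, _ in triples}
    assert preds == {
        reg.resolve("rdf:type"), reg.resolve("dc:identifier"),
        reg.resolve("rdfs:label"), reg.resolve("dc:title"),
        reg.resolve("foaf:page"), reg.resolve("dc:source"),
    }


def test_ke_without_measurement_method_has_no_mmo_triple(reg):
    model = KnowledgeModel()
    ke = KeyEventEntry(id=3, title="plain event")
    model.kes[3] = ke
    triples = emit.emit_ke(ke, model, reg)
    assert all(str(p) != reg.resolve("mmo:0000000") for _, p, _ in triples)


def test_ke_in_three_aops_gets_three_is_part_of(canonical, reg):
    _, result = canonical
    parents = set(result.main_graph.objects(
        u(reg, "aop.events:1502"), u(reg, "dcterms:isPartOf")))
    assert parents == {u(reg, "aop:212"), u(reg, "aop:274"), u(reg, "aop:275")}


def test_stressor_without_chemicals_has_no_chemical_triple(reg):
    model = KnowledgeModel()
    s = StressorEntry(id=4, title="physical stressor")
    model.stressors[4] = s
    triples = emit.emit_stressor(s, model, reg)
    assert all(str(p) != reg.resolve("aopo:has_chemical_entity")
               for _, p, _ in triples)


def test_chemical_without_xrefs_has_no_exact_match(canonical, reg):
    _, result = canonical
    # gemfibrozil has three mapped databases; drop them to probe the no-xref path
    from aoprdf.emit import emit_chemical
    chem = result.model.chemicals["25812-30-0"]
    triples = emit_chemical(chem, set(), result.model, reg)
    assert all(str(p) != reg.resolve("skos:exactMatch") for _, p, _ in triples)


def test_free_text_terms_are_literals_not_iris(canonical, reg):
    _, result = canonical
    actions = set(result.main_graph.objects(
        u(reg, "aop.events:1502"), u(reg, "pato:0000001")))
    assert actions == {Literal("WIKI:2")}
    taxa = set(result.main_graph.objects(
        u(reg, "aop.events:1502"), u(reg, "ncbitaxon:131567")))
    assert Literal("WCS_9606") in taxa
    assert u(reg, "ncbitaxon:10116") in taxa


def test_type_totals_equal_model_collection_sizes(canonical, reg):
    _, result = canonical
    g, m = result.main_graph, result.model
    rdf_type = u(reg, "rdf:type")
    for curie, size in (
        ("aopo:AdverseOutcomePathway", len(m.aops)),
        ("aopo:KeyEvent", len(m.kes)),
        ("aopo:KeyEventRelationship", len(m.kers)),
    ):
        assert len(set(g.subjects(rdf_type, u(reg, curie)))) == size


def test_mie_and_ao_objects_are_subsets_of_key_events(canonical, reg):
    _, result = canonical
    g = result.main_graph
    for aop in g.subjects(u(reg, "rdf:type"), u(reg, "aopo:AdverseOutcomePathway")):
        kes = set(g.objects(aop, u(reg, "aopo:has_key_event")))
        mies = set(g.objects(aop, u(reg, "aopo:has_molecular_initiating_event")))
        aos = set(g.objects(aop, u(reg, "aopo:has_adverse_outcome")))
        assert mies <= kes and aos <= kes


def test_internal_link_objects_are_typed_subjects(canonical, reg):
    """Referential closure over the combined main + gene graphs."""
    _, result = canonical
    union = Graph()
    for g in (result.main_graph, result.gene_graph):
        for t in g:
            union.add(t)
    link_preds = {URIRef(i) for i in reg.internal_link_predicates()}
    typed = set(union.subjects(u(reg, "rdf:type"), None))
    for s, p, o in union:
        if p in link_preds and isinstance(o, URIRef):
            assert o in typed, f"untyped link target {o} via {p}"


def test_main_graph_predicates_stay_within_the_schema(canonical, reg):
    _, result = canonical
    allowed = {reg.resolve("rdf:type")}
    for kind in ("aop", "ke", "ker", "stressor", "chemical", "term"):
        allowed |= {reg.resolve(r.predicate) for r in reg.schema_for(kind)}
    used = {str(p) for p in result.main_graph.predicates(None, None)}
    assert used <= allowed


def test_serialization_is_byte_identical_across_runs(canonical, tmp_path):
    bundle, first = canonical
    from aoprdf.xrefs import static_backend
    second = pipeline.convert(
        bundle.xml_path, hgnc_table=bundle.hgnc_path, pr_table=bundle.pr_path,
        backend=static_backend(bundle.xref_path), outdir=tmp_path / "again",
    )
    for name, path in first.files.items():
        assert (tmp_path / "again" / name).read_bytes() == path.read_bytes()


def test_serialize_parse_serialize_is_a_fixed_point(canonical, reg):
    _, result = canonical
    for graph in (result.main_graph, result.gene_graph, result.void_graph):
        text1 = turtle_text(graph, reg)
        reparsed = Graph()
        reparsed.parse(data=text1, format="turtle")
        assert turtle_text(reparsed, reg) == text1
        assert len(reparsed) == len(graph)  # set semantics, no duplicates


def test_empty_graph_serializes_to_empty_prefix_only_text(reg):
    text = turtle_text(Graph(), reg)
    g = Graph()
    g.parse(data=text, format="turtle")
    assert len(g) == 0


def test_literal_escaping_round_trips(reg):
    g = Graph()
    s = URIRef(reg.resolve("aop:1"))
    nasty = 'line1\nline2\t"quoted" back\\slash'
    g.add((s, URIRef(reg.resolve("dc:description")), Literal(nasty)))
    text = turtle_text(g, reg)
    g2 = Graph()
    g2.parse(data=text, format="turtle")
    assert list(g2)[0][2] == Literal(nasty)


def test_void_counts_match_the_actual_graphs(canonical, reg):
    _, result = canonical
    v = result.void_graph
    triples_pred = u(reg, "void:triples")
    datasets = {
        str(d): int(next(v.objects(d, triples_pred)))
        for d in v.subjects(u(reg, "rdf:type"), u(reg, "void:Dataset"))
    }
    by_name = {name.rsplit("/", 1)[-1]: n for name, n in datasets.items()}
    assert by_name["AOP-Wiki.ttl"] == len(result.main_graph)
    assert by_name["AOP-Wiki-genes.ttl"] == len(result.gene_graph)
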