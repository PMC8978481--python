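"""Turtle validation, SPARQL statistics and the query catalog."""

import pytest
from rdflib import Graph
from rdflib.plugins.sparql import prepareQuery

from aoprdf.qc import compute_stats, query_catalog, validate_files


def test_generated_output_validates_clean(canonical):
    _, result = canonical
    report = validate_files(list(result.files.values()))
    assert report.syntax_ok and report.ok
    assert report.datatype_errors == [] and report.dangling_links == []
    # triple count is over the union (identifier typings recur across files)
    union = Graph()
    for g in (result.main_graph, result.gene_graph, result.void_graph):
        for t in g:
            union.add(t)
    assert report.triples == len(union)


def test_corrupted_datetime_yields_one_datatype_error(canonical, tmp_path):
    _, result = canonical
    text = result.files["AOP-Wiki.ttl"].read_text()
    corrupted = text.replace("2016-11-29T18:41:16", "2016-11-29Tnot:a:time", 1)
    assert corrupted != text
    p = tmp_path / "corrupt.ttl"
    p.write_text(corrupted)
    report = validate_files([p])
    assert report.syntax_ok
    assert len(report.datatype_errors) == 1
    assert "dateTime" in report.datatype_errors[0][1]


def test_truncated_file_fails_syntax_and_short_circuits(canonical, tmp_path):
    _, result = canonical
    text = result.files["AOP-Wiki.ttl"].read_text()
    p = tmp_path / "truncated.ttl"
    p.write_text(text[: len(text) // 2])
    report = validate_files([p])
    assert not report.syntax_ok
    assert report.datatype_errors == [] and report.dangling_links == []
    assert not report.ok


def test_dangling_link_is_reported(tmp_path, reg):
    p = tmp_path / "dangling.ttl"
    p.write_text(
        "@prefix aopo: <http://aopkb.org/aop_ontology#> .\n"
        "@prefix aop: <https://identifiers.org/aop/> .\n"
        "@prefix ev: <https://identifiers.org/aop.events/> .\n"
        "aop:1 a aopo:AdverseOutcomePathway ; aopo:has_key_event ev:99 .\n"
    )
    report = validate_files([p])
    assert report.syntax_ok
    assert report.dangling_links == ["https://identifiers.org/aop.events/99"]


def test_stats_equal_brute_force_iteration(canonical, reg):
    _, result = canonical
    graphs = [result.main_graph, result.gene_graph, result.void_graph]
    stats = compute_stats(graphs)

    union = Graph()
    for g in graphs:
        for t in g:
            union.add(t)
    assert stats.totals["triples"] == len(union)
    assert stats.totals["subjects"] == len({s for s, _, _ in union})
    assert stats.totals["predicates"] == len({p for _, p, _ in union})
    assert stats.totals["objects"] == len({o for _, _, o in union})

    by_type: dict[str, set] = {}
    for s, p, o in union:
        if str(p).endswith("22-rdf-syntax-ns#type"):
            by_type.setdefault(str(o), set()).add(s)
    assert stats.subject_type_counts == {t: len(v) for t, v in by_type.items()}

    freq: dict[str, int] = {}
    for _, p, _ in union:
        freq[str(p)] = freq.get(str(p), 0) + 1
    assert stats.predicate_frequency == freq


def test_linkout_counts_partition_exact_match_targets(canonical, reg):
    _, result = canonical
    stats = compute_stats([result.main_graph, result.gene_graph])
    # one exactMatch per xref supplied by the static table
    total_links = sum(stats.linkout_counts.values())
    expected = (
        sum(len(v) for v in result.chemical_xrefs.values())
        + sum(len(v) for v in result.gene_xrefs.values())
        + sum(len(v) for v in result.pr_xrefs.values())
    )
    assert total_links == expected
    assert set(stats.linkout_counts) <= set(reg.chemical_db_types) | set(reg.gene_db_types)


def test_stats_on_empty_graph_are_zero():
    stats = compute_stats(Graph())
    assert stats.totals == {"triples": 0, "subjects": 0, "predicates": 0, "objects": 0}
    assert stats.linkout_counts == {} and stats.subject_type_counts == {}


def test_catalog_queries_parse_and_run_offline(canonical):
    _, result = canonical
    entries = query_catalog()
    assert entries, "catalog must not be empty"
    names = {e.name for e in entries}
    assert {"count_totals", "subject_types", "linkouts_by_type"} <= names
    for entry in entries:
        if entry.category == "federated":
            continue
        prepareQuery(entry.text)  # must parse
        list(result.main_graph.query(entry.text))  # and run


def test_federated_template_declares_a_service_clause():
    federated = [e for e in query_catalog() if e.category == "federated"]
    assert federated
    for entry in federated:
        assert "SERVICE" in entry.text
        assert entry.network_required


def test_validation_accepts_paths_and_reports_files(canonical):
    _, result = canonical
    paths = [str(p) for p in result.files.values()]
    report = validate_files(paths)
    assert report.files == paths
    assert isinstance(report.text(), str) and "syntax: ok" in report.text()
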