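"""Fixture generation: determinism, truth bookkeeping, decoy safety."""

import pytest

from aoprdf import fixtures, pipeline
from aoprdf.fixtures import FixtureConfig, generate_fixture
from aoprdf.model import parse_aopwiki_xml
from aoprdf.xrefs import static_backend


def test_zero_counts_give_an_empty_valid_document(tmp_path):
    config = FixtureConfig(n_aops=0, n_stressors=0, n_chemicals=0, seed=1)
    bundle = generate_fixture(config, tmp_path)
    model = parse_aopwiki_xml(bundle.xml_path)
    assert not model.aops and not model.kes and not model.chemicals
    assert bundle.truth.counts["aops"] == 0


def test_same_seed_means_byte_identical_bundle(tmp_path):
    config = FixtureConfig(seed=42)
    a = generate_fixture(config, tmp_path / "a")
    b = generate_fixture(FixtureConfig(seed=42), tmp_path / "b")
    for pa, pb in (
        (a.xml_path, b.xml_path), (a.hgnc_path, b.hgnc_path),
        (a.pr_path, b.pr_path), (a.xref_path, b.xref_path),
        (a.truth_path, b.truth_path),
    ):
        assert pa.read_bytes() == pb.read_bytes()
    c = generate_fixture(FixtureConfig(seed=43), tmp_path / "c")
    assert c.xml_path.read_bytes() != a.xml_path.read_bytes()


def test_inconsistent_config_is_rejected():
    with pytest.raises(ValueError, match="MIE and an AO"):
        FixtureConfig(kes_per_aop=1).validate()
    with pytest.raises(ValueError, match="within"):
        FixtureConfig(decoy_rate=1.5).validate()


def test_counts_in_truth_match_the_parsed_model(random_converted):
    bundle, result = random_converted
    truth, m = bundle.truth, result.model
    assert truth.counts["aops"] == len(m.aops)
    assert truth.counts["kes"] == len(m.kes)
    assert truth.counts["kers"] == len(m.kers)
    assert truth.counts["stressors"] == len(m.stressors)
    assert truth.counts["chemicals"] == len(m.chemicals)
    assert truth.counts["terms"] == len(m.terms)


def test_pipeline_reproduces_planted_matches_exactly(random_converted):
    bundle, result = random_converted
    got: dict = {}
    for (kind, eid, field), ms in result.matches.items():
        got.setdefault(kind, {}).setdefault(str(eid), {})[field] = sorted(
            {m.hgnc_id for m in ms}
        )
    assert got == bundle.truth.matches


def test_pipeline_reproduces_planted_xrefs_exactly(random_converted):
    bundle, result = random_converted
    got_chem = {
        cas: sorted([x.target_db, x.target_id] for x in xs)
        for cas, xs in result.chemical_xrefs.items()
    }
    assert got_chem == {k: sorted(v) for k, v in bundle.truth.chemical_xrefs.items()}
    got_gene = {
        g: sorted([x.target_db, x.target_id] for x in xs)
        for g, xs in result.gene_xrefs.items()
    }
    assert got_gene == {k: sorted(v) for k, v in bundle.truth.gene_xrefs.items()}


def test_gene_link_triple_count_matches_truth(random_converted, reg):
    bundle, result = random_converted
    link = reg.uri("edam:data_1025")
    n = len(list(result.gene_graph.triples((None, link, None))))
    assert n == bundle.truth.counts["gene_link_triples"]


@pytest.mark.parametrize("seed", [0, 1, 99])
def test_no_decoy_token_is_ever_matched(tmp_path, seed):
    config = FixtureConfig(seed=seed, decoy_rate=1.0, genes_min=1)
    bundle = generate_fixture(config, tmp_path / str(seed))
    result = pipeline.convert(
        bundle.xml_path, hgnc_table=bundle.hgnc_path,
        backend=static_backend(bundle.xref_path),
    )
    assert bundle.truth.decoys, "decoy_rate=1.0 must plant decoys"
    surfaces = {
        m.surface_form for ms in result.matches.values() for m in ms
    }
    for decoy in bundle.truth.decoys:
        assert decoy not in surfaces
    # and the planted matches are still exactly the truth
    got: dict = {}
    for (kind, eid, field), ms in result.matches.items():
        got.setdefault(kind, {}).setdefault(str(eid), {})[field] = sorted(
            {m.hgnc_id for m in ms}
        )
    assert got == bundle.truth.matches


def test_canonical_bundle_is_self_consistent(tmp_path):
    bundle = fixtures.canonical_fixture(tmp_path)
    model = parse_aopwiki_xml(bundle.xml_path)
    assert model.report.dangling == {}
    assert 38 in model.aops and 1502 in model.kes and 865 in model.kers
    assert model.aops[38].mie_ids == [244]
    assert "103-90-2" in model.chemicals
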