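"""Symbol dictionary construction, boundary-aware text scanning, PR mapping."""

import random

import pytest

from aoprdf.genes import (
    HgncRecord,
    build_symbol_dictionary,
    load_pr_mapping,
    map_pr_term,
    scan_text,
    unique_gene_ids,
)
from conftest import brute_force_scan

RECORDS = [
    HgncRecord("HGNC:12591", "UROD", "uroporphyrinogen decarboxylase"),
    HgncRecord("HGNC:395", "ALAD", "aminolevulinate dehydratase"),
    HgncRecord("HGNC:11998", "TP53", "tumor protein p53", ("p53",)),
]


@pytest.fixture()
def small_dict():
    return build_symbol_dictionary(RECORDS)


def found(text, d):
    return {m.hgnc_id for m in scan_text(text, d)}


def test_symbol_matches_only_at_token_boundaries(small_dict):
    assert found("Reduced UROD enzyme activity", small_dict) == {"UROD"}
    assert found("SURODX", small_dict) == set()
    assert found("the sURODx complex", small_dict) == set()
    assert found("UROD/ALAD pathway", small_dict) == {"UROD", "ALAD"}
    assert found("(UROD)", small_dict) == {"UROD"}
    assert found("UROD", small_dict) == {"UROD"}


def test_empty_text_yields_no_matches(small_dict):
    assert scan_text("", small_dict) == set()


def test_symbols_are_case_sensitive_names_are_not(small_dict):
    assert found("urod levels", small_dict) == set()
    assert found("Tumor Protein P53 is mutated", small_dict) == {"TP53"}
    assert found("TP53 and p53 both written", small_dict) == {"TP53"}


def test_match_spans_address_the_scanned_text(small_dict):
    (m,) = scan_text("see UROD here", small_dict)
    assert "see UROD here"[m.start:m.end] == m.surface_form == "UROD"


def test_alias_collision_resolves_to_approved_symbol_owner():
    records = [
        HgncRecord("HGNC:2", "AAA1", "", ("MAA",)),
        HgncRecord("HGNC:1", "MAA", "melanoma associated antigen gene"),
    ]
    d = build_symbol_dictionary(records)
    assert d.lookup("MAA") == "MAA"
    assert len(d.collisions) == 1 and "MAA" in d.collisions[0]


def test_alias_only_collision_resolves_to_lowest_numeric_id():
    records = [
        HgncRecord("HGNC:20", "GENB", "", ("SHARED",)),
        HgncRecord("HGNC:10", "GENA", "", ("SHARED",)),
    ]
    d = build_symbol_dictionary(records)
    assert d.lookup("SHARED") == "GENA"


def test_stop_list_and_min_length_filter_forms():
    records = [HgncRecord("HGNC:1", "CA", ""), HgncRecord("HGNC:2", "TP53", "")]
    d = build_symbol_dictionary(records, min_length=3)
    assert "CA" not in d and "TP53" in d
    d2 = build_symbol_dictionary(records, stop_list={"TP53"})
    assert "TP53" not in d2


def test_scan_matches_brute_force_oracle_on_random_texts(small_dict):
    rng = random.Random(20210101)
    vocab = ["UROD", "ALAD", "TP53", "p53", "urod", "surodx", "xTP53z",
             "tumor", "protein", "p53,", "(UROD)", "the", "enzyme", "alad-"]
    for _ in range(200):
        text = " ".join(rng.choice(vocab) for _ in range(rng.randint(0, 40)))
        got = {(m.hgnc_id, m.start, m.end) for m in scan_text(text, small_dict)}
        assert got == brute_force_scan(text, small_dict)


def test_adding_an_entry_never_removes_matches(small_dict):
    text = "UROD and ALAD and NEWGENE"
    before = {m.hgnc_id for m in scan_text(text, small_dict)}
    small_dict.add_form("NEWGENE", "NEWGENE", case_sensitive=True)
    after = {m.hgnc_id for m in scan_text(text, small_dict)}
    assert before <= after and "NEWGENE" in after


def test_deduplication_keeps_one_id_per_field(small_dict):
    matches = scan_text("UROD then UROD again", small_dict)
    assert len(matches) == 2  # audit keeps both occurrences
    assert unique_gene_ids(matches) == {"UROD"}


def test_hgnc_table_missing_columns_is_an_error(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("hgnc_id\tgene\nHGNC:1\tX\n")
    with pytest.raises(ValueError, match="missing columns"):
        build_symbol_dictionary(p)


def test_pr_mapping_examples(tmp_path):
    p = tmp_path / "pr.tsv"
    p.write_text(
        "PR:000008478\tUniProtKB:Q9UKV0\tis_a\n"
        "PR:000008478\tHGNC:HDAC9\tis_a\n"
        "PR:000008478\tNCBIGene:9734\tis_a\n"
        "PR:000000042\tUniProtKB:P00042\tis_a\n"
        "PR:000000042\tMGI:12345\tis_a\n"  # out-of-scope target, skipped
    )
    table = load_pr_mapping(p)
    full = map_pr_term("pr:000008478", table)
    assert {(x.target_db, x.target_id) for x in full} == {
        ("uniprot", "Q9UKV0"), ("hgnc", "HDAC9"), ("ncbigene", "9734"),
    }
    assert map_pr_term("pr:000099999", table) == set()
    only_one = map_pr_term("pr:000000042", table)
    assert [(x.target_db, x.target_id) for x in only_one] == [("uniprot", "P00042")]
    with pytest.raises(ValueError, match="PRotein Ontology"):
        map_pr_term("go:0008150", table)


# adversarial property check: the matcher and the independent oracle agree on
# arbitrary separator-rich text, including unicode and pathological nesting
try:
    from hypothesis import given, settings, strategies as st

    _ALPHABET = "URODALADTP53p53surodx ()[]{}.,;:/\"'-\n\té"

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.text(alphabet=_ALPHABET, max_size=300))
    def test_scan_agrees_with_oracle_on_adversarial_text(text):
        d = build_symbol_dictionary(RECORDS)
        got = {(m.hgnc_id, m.start, m.end) for m in scan_text(text, d)}
        assert got == brute_force_scan(text, d)

except ImportError:  # pragma: no cover - hypothesis is an optional test extra
    pass
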