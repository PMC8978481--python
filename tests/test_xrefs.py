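"""Identifier cross-mapping backends and the database-scope filters."""

import io
import urllib.error

import pytest

from aoprdf.xrefs import (
    CHEMICAL_DBS,
    GENE_DBS,
    TransportError,
    XrefRecord,
    http_backend,
    map_chemical,
    map_gene,
    static_backend,
)


@pytest.fixture()
def table(tmp_path):
    p = tmp_path / "xrefs.tsv"
    p.write_text(
        "cas\t103-90-2\tchebi\t46195\n"
        "cas\t103-90-2\tchemspider\t1906\n"
        "cas\t103-90-2\twikidata\tQ57055\n"
        "cas\t103-90-2\tchebi\t46195\n"          # duplicate row
        "hgnc\tUROD\tncbigene\t7389\n"
        "hgnc\tUROD\tuniprot\tP06132\n"
        "hgnc\tUROD\tuniprot\tP06132-2\n"        # second accession
        "hgnc\tUROD\tensembl\tENSG00000126088\n"
    )
    return p


def test_static_backend_returns_exactly_the_table_rows(table):
    b = static_backend(table)
    got = b.lookup("103-90-2", "cas", CHEMICAL_DBS)
    assert {(x.target_db, x.target_id) for x in got} == {
        ("chebi", "46195"), ("chemspider", "1906"), ("wikidata", "Q57055"),
    }
    assert b.lookup("0-00-0", "cas", CHEMICAL_DBS) == set()


def test_multiple_accessions_are_all_returned(table):
    got = map_gene("UROD", static_backend(table))
    uniprot = {x.target_id for x in got if x.target_db == "uniprot"}
    assert uniprot == {"P06132", "P06132-2"}
    assert {x.target_db for x in got} <= GENE_DBS


def test_mapping_is_idempotent_and_deduplicated(table):
    b = static_backend(table)
    first = map_chemical("103-90-2", b)
    second = map_chemical("103-90-2", b)
    assert first == second
    assert len([x for x in first if x.target_db == "chebi"]) == 1


def test_malformed_row_raises_with_line_number(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("cas\t103-90-2\tchebi\t46195\ncas\tonly-two\n")
    with pytest.raises(ValueError, match=":2"):
        static_backend(p)


def test_unknown_db_token_is_kept_with_warning(tmp_path, caplog):
    p = tmp_path / "odd.tsv"
    p.write_text("cas\t103-90-2\tnotadb\tX1\n")
    with caplog.at_level("WARNING"):
        b = static_backend(p)
    assert "notadb" in caplog.text
    assert b.lookup("103-90-2", "cas", {"notadb"})  # row kept


def test_out_of_scope_target_is_filtered_from_results():
    class Leaky:
        name = provenance = "leaky"

        def lookup(self, source_id, source_db, target_dbs):
            return {
                XrefRecord("cas", source_id, "chebi", "1"),
                XrefRecord("cas", source_id, "ncbigene", "2"),  # gene db for a chemical
            }

    got = map_chemical("103-90-2", Leaky())
    assert {x.target_db for x in got} == {"chebi"}


class _Resp(io.BytesIO):
    def __enter__(self):
        return self

    def __exit__(self, *a):
        return False


def test_http_backend_parses_two_column_response(monkeypatch):
    body = b"CHEBI:46195\tChEBI\n1906\tChemSpider\nXX\tNotAKnownSource\n"
    monkeypatch.setattr(
        "urllib.request.urlopen", lambda url, timeout: _Resp(body)
    )
    got = http_backend("http://bridge.example").lookup(
        "103-90-2", "cas", CHEMICAL_DBS
    )
    assert {(x.target_db, x.target_id) for x in got} == {
        ("chebi", "46195"), ("chemspider", "1906"),
    }


def test_http_404_means_no_mapping(monkeypatch):
    def raise_404(url, timeout):
        raise urllib.error.HTTPError(url, 404, "not found", None, None)

    monkeypatch.setattr("urllib.request.urlopen", raise_404)
    assert http_backend("http://bridge.example").lookup(
        "0-00-0", "cas", CHEMICAL_DBS
    ) == set()


def test_http_timeout_is_a_transport_error(monkeypatch):
    def raise_timeout(url, timeout):
        raise TimeoutError("timed out")

    monkeypatch.setattr("urllib.request.urlopen", raise_timeout)
    with pytest.raises(TransportError):
        http_backend("http://bridge.example").lookup(
            "103-90-2", "cas", CHEMICAL_DBS
        )
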