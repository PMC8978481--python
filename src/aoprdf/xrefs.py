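"""Identifier cross-mapping for chemicals (CAS) and genes (HGNC symbols).

Mirrors the identifier-mapping step of the conversion: each chemical's CAS
number is expanded to identifiers in nine external chemical databases, and
each text-mapped gene symbol to NCBI Gene, UniProt and Ensembl, through a
pluggable :class:`MapperBackend`. The default backend is an offline static
table; a BridgeDb-compatible HTTP backend is available for live services.
Results outside the allowed database sets are filtered (and logged), and all
lookups are pure for fixed backend state.
"""

from __future__ import annotations

import logging
import urllib.error
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

logger = logging.getLogger(__name__)

__all__ = [
    "XrefRecord",
    "MapperBackend",
    "StaticTableBackend",
    "HttpBackend",
    "TransportError",
    "static_backend",
    "http_backend",
    "map_chemical",
    "map_gene",
    "CHEMICAL_DBS",
    "GENE_DBS",
]

#: chemical databases covered by the mapping service (besides CAS itself)
CHEMICAL_DBS = frozenset({
    "chebi", "chemspider", "wikidata", "chembl.compound",
    "pubchem.compound", "drugbank", "kegg.compound", "lipidmaps", "hmdb",
})
#: gene/protein databases reachable from an HGNC symbol
GENE_DBS = frozenset({"ncbigene", "uniprot", "ensembl"})

# BridgeDb system codes -> registry database tokens (declarative, one place)
BRIDGEDB_SYSTEM_CODES = {
    "Ca": "cas",
    "Ce": "chebi",
    "Cs": "chemspider",
    "Wd": "wikidata",
    "Cl": "chembl.compound",
    "Cpc": "pubchem.compound",
    "Dr": "drugbank",
    "Ck": "kegg.compound",
    "Lm": "lipidmaps",
    "Ch": "hmdb",
    "H": "hgnc",
    "L": "ncbigene",
    "S": "uniprot",
    "En": "ensembl",
}
# BridgeDb datasource display names (as returned by the xrefs call)
BRIDGEDB_DATASOURCE_NAMES = {
    "CAS": "cas",
    "ChEBI": "chebi",
    "ChemSpider": "chemspider",
    "Wikidata": "wikidata",
    "ChEMBL compound": "chembl.compound",
    "PubChem-compound": "pubchem.compound",
    "DrugBank": "drugbank",
    "KEGG Compound": "kegg.compound",
    "LIPID MAPS": "lipidmaps",
    "HMDB": "hmdb",
    "HGNC": "hgnc",
    "Entrez Gene": "ncbigene",
    "Uniprot-TrEMBL": "uniprot",
    "Uniprot-SwissProt": "uniprot",
    "Ensembl": "ensembl",
}
# identifier prefixes some services prepend to the local id
_STRIP_PREFIXES = ("CHEBI:", "CHEMBL:", "HMDB:", "HGNC:")


class TransportError(RuntimeError):
    """Backend could not be reached; retriable, distinct from 'no mapping'."""


@dataclass(frozen=True, order=True)
class XrefRecord:
    """One cross-database identifier link (source id → target database id)."""

    source_db: str
    source_id: str
    target_db: str
    target_id: str


@runtime_checkable
class MapperBackend(Protocol):
    """Lookup contract: unknown sources yield the empty set, never an error."""

    name: str
    provenance: str

    def lookup(
        self, source_id: str, source_db: str, target_dbs: Iterable[str]
    ) -> set[XrefRecord]: ...


_ALL_DBS = CHEMICAL_DBS | GENE_DBS | {"cas", "hgnc", "inchikey", "comptox"}


class StaticTableBackend:
    """Offline backend reading a 4-column TSV
    (source_db, source_id, target_db, target_id); duplicate rows collapse."""

    def __init__(self, table: str | Path):
        self.name = "static"
        self.provenance = f"static table {table}"
        self._rows: dict[tuple[str, str], set[XrefRecord]] = {}
        with open(table, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 4 or not all(parts):
                    raise ValueError(
                        f"{table}:{lineno}: expected 4 tab-separated columns, "
                        f"got {line!r}"
                    )
                sdb, sid, tdb, tid = parts
                for db in (sdb, tdb):
                    if db not in _ALL_DBS:
                        logger.warning(
                            "%s:%d: unknown database token %r (row kept)",
                            table, lineno, db,
                        )
                rec = XrefRecord(sdb, sid, tdb, tid)
                self._rows.setdefault((sdb, sid), set()).add(rec)

    def lookup(self, source_id, source_db, target_dbs) -> set[XrefRecord]:
        wanted = set(target_dbs)
        return {
            r for r in self._rows.get((source_db, source_id), set())
            if r.target_db in wanted
        }


class HttpBackend:
    """BridgeDb-REST-dialect backend:
    ``GET {base}/{organism}/xrefs/{systemCode}/{id}`` returning two-column
    plain text (identifier TAB datasource name). 404 means "no mapping"."""

    def __init__(self, base_url: str, organism: str = "Human", timeout: float = 10.0):
        self.name = "bridgedb-http"
        self.provenance = f"BridgeDb service at {base_url}"
        self.base_url = base_url.rstrip("/")
        self.organism = organism
        self.timeout = timeout

    def _system_code(self, db: str) -> str:
        for code, token in BRIDGEDB_SYSTEM_CODES.items():
            if token == db:
                return code
        raise ValueError(f"no BridgeDb system code for database {db!r}")

    def lookup(self, source_id, source_db, target_dbs) -> set[XrefRecord]:
        url = (
            f"{self.base_url}/{self.organism}/xrefs/"
            f"{self._system_code(source_db)}/{source_id}"
        )
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                body = resp.read().decode("utf-8")
        except urllib.error.HTTPError as exc:
            if exc.code == 404:  # BridgeDb convention: unknown id
                return set()
            raise TransportError(f"GET {url} failed: HTTP {exc.code}") from exc
        except (urllib.error.URLError, TimeoutError, OSError) as exc:
            raise TransportError(f"GET {url} failed: {exc}") from exc

        wanted = set(target_dbs)
        out: set[XrefRecord] = set()
        for line in body.splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                logger.warning("unparseable xrefs line %r from %s", line, url)
                continue
            ident, source_name = parts
            token = BRIDGEDB_DATASOURCE_NAMES.get(source_name)
            if token is None:
                logger.debug("datasource %r not in scope, skipped", source_name)
                continue
            if token in wanted:
                out.add(XrefRecord(source_db, source_id, token, _strip_prefix(ident)))
        return out


def _strip_prefix(ident: str) -> str:
    for p in _STRIP_PREFIXES:
        if ident.startswith(p):
            return ident[len(p):]
    return ident


def static_backend(table: str | Path) -> StaticTableBackend:
    return StaticTableBackend(table)


def http_backend(base_url: str, organism: str = "Human") -> HttpBackend:
    return HttpBackend(base_url, organism=organism)


def _map(source_id, source_db, backend, allowed) -> set[XrefRecord]:
    records = backend.lookup(source_id, source_db, allowed)
    kept = set()
    for r in records:
        if r.target_db in allowed:
            kept.add(r)
        else:
            logger.warning(
                "xref %s:%s -> %s:%s outside the allowed database set, filtered",
                source_db, source_id, r.target_db, r.target_id,
            )
    return kept


def map_chemical(cas: str, backend: MapperBackend) -> set[XrefRecord]:
    """All direct mappings of one CAS number into the nine chemical databases."""
    return _map(cas, "cas", backend, CHEMICAL_DBS)


def map_gene(hgnc_id: str, backend: MapperBackend) -> set[XrefRecord]:
    """All direct mappings of one HGNC symbol into NCBI Gene/UniProt/Ensembl."""
    return _map(hgnc_id, "hgnc", backend, GENE_DBS)
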