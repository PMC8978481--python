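"""Gene identification in free text and protein-term identifier mapping.

Two enrichment routes add gene/protein identifiers to the knowledge graph:

1. *Dictionary text matching.* A surface-form dictionary is built from an
   HGNC gene table (approved symbols, full names, alias symbols and names).
   Five free-text fields of key events and key event relationships are
   scanned for exact, boundary-delimited occurrences; each match contributes
   an HGNC identifier to the entity. Matching is deliberately simple exact
   matching, not NER: symbols match case-sensitively (symbol/abbreviation
   collisions are the known failure mode of this approach), names and
   multi-word aliases case-insensitively. A form matches only when flanked
   by separator characters or the string boundary, which is equivalent to
   enumerating separator variants around each symbol without the dictionary
   blow-up.

2. *PRotein Ontology mapping.* Biological-object annotations that carry PR
   terms are mapped to UniProt, HGNC and NCBI Gene identifiers through a
   promapping-style table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from .vocab import Curie
from .xrefs import XrefRecord

logger = logging.getLogger(__name__)

__all__ = [
    "HgncRecord",
    "SymbolDictionary",
    "TextMatch",
    "PrMappingTable",
    "build_symbol_dictionary",
    "scan_text",
    "load_pr_mapping",
    "map_pr_term",
    "SCANNED_FIELDS",
    "SEPARATORS",
]

#: the five entity text fields scanned for gene mentions
SCANNED_FIELDS = (
    "ke_description",
    "mie_ao_section",
    "ker_description",
    "biological_plausibility",
    "empirical_support",
)

#: characters that count as token boundaries around a gene mention
SEPARATORS = " \t\n\r\x0b\x0c()[]{}.,;:/\"'-"

# form-kind priority for collision resolution (lower wins)
_PRIORITY = {"symbol": 0, "name": 1, "alias_symbol": 2, "alias_name": 2}


@dataclass(frozen=True)
class HgncRecord:
    hgnc_id: str
    symbol: str
    name: str = ""
    alias_symbols: tuple[str, ...] = ()
    alias_names: tuple[str, ...] = ()


@dataclass(frozen=True)
class TextMatch:
    """One boundary-delimited occurrence of a dictionary form.

    ``start:end`` is a half-open 0-based span; ``text[start:end]`` equals
    ``surface_form`` (up to case for case-insensitive forms)."""

    hgnc_id: str
    surface_form: str
    field_name: str
    start: int
    end: int


@dataclass
class _Form:
    text: str
    hgnc_id: str   # approved symbol used as the graph-facing key
    numeric_id: int
    kind: str      # symbol | name | alias_symbol | alias_name

    @property
    def case_sensitive(self) -> bool:
        return self.kind in ("symbol", "alias_symbol")


@dataclass
class SymbolDictionary:
    """Surface-form → HGNC lookup with boundary-aware matching."""

    forms: dict[str, str] = dc_field(default_factory=dict)      # exact-case forms
    ci_forms: dict[str, str] = dc_field(default_factory=dict)   # lowercased forms
    collisions: list[str] = dc_field(default_factory=list)
    min_length: int = 2
    _patterns: list[tuple[re.Pattern, str, str]] = dc_field(
        default_factory=list, repr=False
    )

    def __len__(self) -> int:
        return len(self.forms) + len(self.ci_forms)

    def __contains__(self, form: str) -> bool:
        return form in self.forms or form.lower() in self.ci_forms

    def lookup(self, form: str) -> str | None:
        hit = self.forms.get(form)
        if hit is None:
            hit = self.ci_forms.get(form.lower())
        return hit

    def add_form(self, form: str, hgnc_id: str, case_sensitive: bool) -> None:
        """Register one surface form (used by tests and incremental builds);
        existing mappings are never displaced."""
        if case_sensitive:
            self.forms.setdefault(form, hgnc_id)
        else:
            self.ci_forms.setdefault(form.lower(), hgnc_id)
        self._patterns = []

    def _compiled(self) -> list[tuple[re.Pattern, str, str]]:
        if not self._patterns:
            sep = re.escape(SEPARATORS)
            before = f"(?<![^{sep}])"
            after = f"(?![^{sep}])"
            pats = []
            # the form sits inside a lookahead so overlapping occurrences of
            # the same (multi-word) form are all found
            for form, hgnc in sorted(self.forms.items()):
                pats.append((
                    re.compile(f"{before}(?=({re.escape(form)}){after})"),
                    form, hgnc,
                ))
            for form, hgnc in sorted(self.ci_forms.items()):
                pats.append((
                    re.compile(
                        f"{before}(?=({re.escape(form)}){after})", re.IGNORECASE
                    ),
                    form, hgnc,
                ))
            self._patterns = pats
        return self._patterns

    def scan(self, text: str, field_name: str = "ke_description") -> set[TextMatch]:
        """All boundary-delimited exact occurrences of dictionary forms."""
        if not text:
            return set()
        out: set[TextMatch] = set()
        for pattern, _form, hgnc in self._compiled():
            for m in pattern.finditer(text):
                start, end = m.start(1), m.end(1)
                out.add(
                    TextMatch(
                        hgnc_id=hgnc,
                        surface_form=text[start:end],
                        field_name=field_name,
                        start=start,
                        end=end,
                    )
                )
        return out


def _split_multi(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ()
    return tuple(p.strip() for p in str(value).split("|") if p.strip())


def _numeric_id(hgnc_id: str) -> int:
    m = re.search(r"(\d+)$", hgnc_id)
    return int(m.group(1)) if m else 0


def load_hgnc_table(path: str | Path) -> list[HgncRecord]:
    """Read an HGNC gene table: TSV with headers hgnc_id, symbol, name,
    alias_symbol, alias_name (multi-valued columns pipe-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"hgnc_id", "symbol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"HGNC table {path} missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        symbol = getattr(row, "symbol", "").strip()
        if not symbol:
            raise ValueError(f"HGNC table {path}: empty symbol in row {row}")
        records.append(
            HgncRecord(
                hgnc_id=row.hgnc_id.strip(),
                symbol=symbol,
                name=getattr(row, "name", "").strip(),
                alias_symbols=_split_multi(getattr(row, "alias_symbol", "")),
                alias_names=_split_multi(getattr(row, "alias_name", "")),
            )
        )
    symbols = [r.symbol for r in records]
    if len(symbols) != len(set(symbols)):
        dupes = sorted({s for s in symbols if symbols.count(s) > 1})
        raise ValueError(f"HGNC table {path}: duplicate approved symbols {dupes}")
    return records


def build_symbol_dictionary(
    hgnc_table: str | Path | list[HgncRecord],
    min_length: int = 2,
    stop_list: set[str] | None = None,
) -> SymbolDictionary:
    """Build the surface-form dictionary from an HGNC table.

    Collisions (one form claimed by several genes) resolve by form kind
    (approved symbol > name > alias), then by lowest numeric HGNC id; every
    resolution is logged and recorded in ``dictionary.collisions``.
    *stop_list* drops known-ambiguous forms entirely.
    """
    records = (
        hgnc_table
        if isinstance(hgnc_table, list)
        else load_hgnc_table(hgnc_table)
    )
    stop = {s.lower() for s in (stop_list or set())}

    candidates: dict[tuple[str, bool], _Form] = {}
    collisions: list[str] = []
    for rec in records:
        nid = _numeric_id(rec.hgnc_id)
        forms = [(rec.symbol, "symbol")]
        if rec.name:
            forms.append((rec.name, "name"))
        forms.extend((a, "alias_symbol") for a in rec.alias_symbols)
        forms.extend((a, "alias_name") for a in rec.alias_names)
        for text, kind in forms:
            if len(text) < min_length or text.lower() in stop:
                continue
            cs = kind in ("symbol", "alias_symbol")
            key = (text if cs else text.lower(), cs)
            new = _Form(text=text, hgnc_id=rec.symbol, numeric_id=nid, kind=kind)
            old = candidates.get(key)
            if old is None:
                candidates[key] = new
            elif old.hgnc_id != new.hgnc_id:
                winner, loser = sorted(
                    (old, new), key=lambda f: (_PRIORITY[f.kind], f.numeric_id)
                )
                candidates[key] = winner
                msg = (
                    f"surface form {text!r} claimed by {old.hgnc_id} ({old.kind}) "
                    f"and {new.hgnc_id} ({new.kind}); resolved to {winner.hgnc_id}"
                )
                collisions.append(msg)
                logger.warning(msg)

    d = SymbolDictionary(min_length=min_length, collisions=collisions)
    for (key, cs), form in candidates.items():
        if cs:
            d.forms[key] = form.hgnc_id
        else:
            d.ci_forms[key] = form.hgnc_id
    return d


def scan_text(
    text: str, dictionary: SymbolDictionary, field_name: str = "ke_description"
) -> set[TextMatch]:
    """Scan one text field; see :meth:`SymbolDictionary.scan`."""
    return dictionary.scan(text, field_name)


def unique_gene_ids(matches: set[TextMatch]) -> set[str]:
    """Deduplicate a match set to the HGNC ids used for triple emission."""
    return {m.hgnc_id for m in matches}


# ---------------------------------------------------------------------------
# PRotein Ontology mapping

_PR_TARGET_PREFIXES = {
    "UniProtKB": "uniprot",
    "HGNC": "hgnc",
    "NCBIGene": "ncbigene",
}
_PR_ID_RE = re.compile(r"^PR:\d{9}$")


@dataclass
class PrMappingTable:
    """PR CURIE → gene/protein identifier links (promapping-style)."""

    rows: dict[str, set[XrefRecord]] = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)


def load_pr_mapping(path: str | Path) -> PrMappingTable:
    """Load a promapping-style TSV: PR CURIE, target CURIE, relation.

    Target CURIEs use UniProtKB / HGNC / NCBIGene prefixes (HGNC targets
    carry gene symbols, matching the symbol-keyed gene IRIs of the graph).
    All relation values are treated as mappable; rows with unknown target
    prefixes are logged and skipped.
    """
    table = PrMappingTable()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 columns, got {line!r}"
                )
            pr_id, target = parts[0], parts[1]
            if not _PR_ID_RE.match(pr_id):
                logger.warning("%s:%d: invalid PR id %r, row skipped", path, lineno, pr_id)
                continue
            if ":" not in target:
                logger.warning("%s:%d: malformed target %r, row skipped", path, lineno, target)
                continue
            prefix, local = target.split(":", 1)
            db = _PR_TARGET_PREFIXES.get(prefix)
            if db is None:
                logger.info("%s:%d: target prefix %r out of scope, row skipped",
                            path, lineno, prefix)
                continue
            table.rows.setdefault(pr_id, set()).add(
                XrefRecord(source_db="pr", source_id=pr_id, target_db=db, target_id=local)
            )
    return table


def map_pr_term(pr: Curie | str, table: PrMappingTable) -> set[XrefRecord]:
    """Gene/protein xrefs of one PR biological-object term (empty when the
    term is not in the mapping table)."""
    if isinstance(pr, str):
        pr = Curie.parse(pr)
    if pr.prefix.lower() != "pr":
        raise ValueError(f"not a PRotein Ontology CURIE: {pr}")
    key = f"PR:{pr.local}"
    found = table.rows.get(key, set())
    if not found:
        logger.info("no PR mapping for %s", key)
    return set(found)
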