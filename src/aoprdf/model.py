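"""Typed in-memory knowledge model of one AOP-Wiki-style XML dump.

The wiki's quarterly dump describes adverse outcome pathways (AOPs): ordered
chains of key events (KEs) running from a molecular initiating event (MIE) to
an adverse outcome (AO), connected by key event relationships (KERs) and
triggered by stressors, most of which are chemicals with CAS numbers. KEs
additionally carry structured "component" annotations (biological process /
object / action ontology terms), cell- and organ-term contexts, and taxonomic
applicability.

Parsing reads a documented fixture dialect (``<data><aop id="38">...``) whose
element names can be remapped through a dialect configuration, so real dumps
with different element spellings can be adapted without code changes.
Malformed entities are skipped with a warning, never fatally; cross-reference
problems are recorded as dangling references and the entries retained.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field as dc_field
from datetime import datetime
from pathlib import Path

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "AopEntry",
    "KeyEventEntry",
    "KerEntry",
    "StressorEntry",
    "ChemicalEntry",
    "TermEntry",
    "KnowledgeModel",
    "ParseReport",
    "ParseError",
    "parse_aopwiki_xml",
    "model_report",
    "DEFAULT_DIALECT",
    "load_dialect",
]

CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")
INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

TERM_KINDS = ("cell", "organ", "taxonomy", "process", "object", "action")


class ParseError(ValueError):
    """Malformed XML input (carries the parser's line number)."""


# ---------------------------------------------------------------------------
# entity types


@dataclass
class AopEntry:
    id: int
    title: str
    alternative_title: str | None = None
    creators: list[str] = dc_field(default_factory=list)
    abstract: str | None = None
    description: str | None = None
    status: str | None = None
    created: datetime | None = None
    modified: datetime | None = None
    ke_ids: list[int] = dc_field(default_factory=list)
    mie_ids: list[int] = dc_field(default_factory=list)
    ao_ids: list[int] = dc_field(default_factory=list)
    ker_ids: list[int] = dc_field(default_factory=list)
    stressor_ids: list[int] = dc_field(default_factory=list)
    sex_applicability: str | None = None
    life_stage: str | None = None
    applicability_text: str | None = None
    quantitative_considerations: str | None = None
    weight_of_evidence: str | None = None
    potential_applications: str | None = None
    overall_assessment: str | None = None
    ke_essentiality: str | None = None


@dataclass
class KeyEventEntry:
    id: int
    title: str
    alternative_title: str | None = None
    bio_level: str | None = None
    description: str | None = None
    mie_ao_section: str | None = None  # MIE/AO-specific free text (gene-scanned)
    measurement_method: str | None = None
    cell_term: str | None = None        # term key
    organ_term: str | None = None
    process_terms: list[str] = dc_field(default_factory=list)
    object_terms: list[str] = dc_field(default_factory=list)
    action_terms: list[str] = dc_field(default_factory=list)
    stressor_ids: list[int] = dc_field(default_factory=list)  # MIEs only
    taxa: list[str] = dc_field(default_factory=list)
    sex_applicability: str | None = None
    life_stage: str | None = None


@dataclass
class KerEntry:
    id: int
    upstream_ke: int
    downstream_ke: int
    description: str | None = None
    biological_plausibility: str | None = None
    empirical_support: str | None = None
    uncertainties: str | None = None
    taxa: list[str] = dc_field(default_factory=list)
    sex_applicability: str | None = None
    life_stage: str | None = None
    created: datetime | None = None
    modified: datetime | None = None


@dataclass
class StressorEntry:
    id: int
    title: str
    description: str | None = None
    chemical_cas: list[str] = dc_field(default_factory=list)
    created: datetime | None = None
    modified: datetime | None = None


@dataclass
class ChemicalEntry:
    cas: str
    name: str
    synonyms: list[str] = dc_field(default_factory=list)
    inchikey: str | None = None
    comptox: str | None = None


@dataclass
class TermEntry:
    """One pre-annotated wiki term (cell-term, organ-term, taxonomy entry or
    KE component). Identity is an ontology CURIE when one exists, otherwise
    the wiki's free-text token (e.g. taxonomy ``WCS_9606``)."""

    kind: str  # one of TERM_KINDS
    label: str
    curie: str | None = None
    free_text: str | None = None

    def __post_init__(self) -> None:
        if (self.curie is None) == (self.free_text is None):
            raise ValueError("exactly one of curie/free_text carries term identity")
        if self.kind not in TERM_KINDS:
            raise ValueError(f"unknown term kind: {self.kind!r}")

    @property
    def key(self) -> str:
        return self.curie if self.curie is not None else self.free_text  # type: ignore[return-value]


@dataclass
class ParseReport:
    """What the parser saw: per-collection parsed/skipped tallies, warnings,
    and dangling cross-references (referenced but never defined)."""

    parsed: dict[str, int] = dc_field(default_factory=dict)
    skipped: dict[str, int] = dc_field(default_factory=dict)
    warnings: list[str] = dc_field(default_factory=list)
    dangling: dict[str, list[str]] = dc_field(default_factory=dict)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)

    def add_dangling(self, kind: str, ref: str) -> None:
        refs = self.dangling.setdefault(kind, [])
        if ref not in refs:
            refs.append(ref)


@dataclass
class KnowledgeModel:
    aops: dict[int, AopEntry] = dc_field(default_factory=dict)
    kes: dict[int, KeyEventEntry] = dc_field(default_factory=dict)
    kers: dict[int, KerEntry] = dc_field(default_factory=dict)
    stressors: dict[int, StressorEntry] = dc_field(default_factory=dict)
    chemicals: dict[str, ChemicalEntry] = dc_field(default_factory=dict)
    terms: dict[str, TermEntry] = dc_field(default_factory=dict)
    snapshot_date: str | None = None
    source_path: str | None = None
    report: ParseReport = dc_field(default_factory=ParseReport)


# ---------------------------------------------------------------------------
# dialect

# The fixture dialect: logical field -> element path. Path syntax:
#   "@attr"            attribute of the entity element itself
#   "tag"              text of a child element
#   "tag@attr"         attribute of each child element named tag
# Multi-valued text fields (creators, synonyms) are split on `delimiter`.
DEFAULT_DIALECT: dict = {
    "root": "data",
    "delimiter": "\n",
    "snapshot_date": "@snapshot-date",
    "aop": {
        "tag": "aop",
        "id": "@id",
        "fields": {
            "title": "title",
            "alternative_title": "alternative-title",
            "creators": "creators",
            "abstract": "abstract",
            "description": "description",
            "status": "status",
            "created": "created",
            "modified": "modified",
            "sex_applicability": "sex-applicability",
            "life_stage": "life-stage",
            "applicability_text": "applicability",
            "quantitative_considerations": "quantitative-considerations",
            "weight_of_evidence": "weight-of-evidence",
            "potential_applications": "potential-applications",
            "overall_assessment": "overall-assessment",
            "ke_essentiality": "ke-essentiality",
            "ke_ids": "key-events/key-event@ref",
            "mie_ids": "molecular-initiating-events/key-event@ref",
            "ao_ids": "adverse-outcomes/key-event@ref",
            "ker_ids": "key-event-relationships/key-event-relationship@ref",
            "stressor_ids": "stressors/stressor@ref",
        },
    },
    "ke": {
        "tag": "key-event",
        "id": "@id",
        "fields": {
            "title": "title",
            "alternative_title": "alternative-title",
            "bio_level": "bio-level",
            "description": "description",
            "mie_ao_section": "mie-ao-section",
            "measurement_method": "measurement-method",
            "cell_term": "cell-term@ref",
            "organ_term": "organ-term@ref",
            "process_terms": "biological-process@ref",
            "object_terms": "biological-object@ref",
            "action_terms": "biological-action@ref",
            "stressor_ids": "stressor@ref",
            "taxa": "taxonomy@ref",
            "sex_applicability": "sex-applicability",
            "life_stage": "life-stage",
        },
    },
    "ker": {
        "tag": "key-event-relationship",
        "id": "@id",
        "fields": {
            "upstream_ke": "upstream@ref",
            "downstream_ke": "downstream@ref",
            "description": "description",
            "biological_plausibility": "biological-plausibility",
            "empirical_support": "empirical-support",
            "uncertainties": "uncertainties",
            "taxa": "taxonomy@ref",
            "sex_applicability": "sex-applicability",
            "life_stage": "life-stage",
            "created": "created",
            "modified": "modified",
        },
    },
    "stressor": {
        "tag": "stressor",
        "id": "@id",
        "fields": {
            "title": "title",
            "description": "description",
            "chemical_cas": "chemical-ref@cas",
            "created": "created",
            "modified": "modified",
        },
    },
    "chemical": {
        "tag": "chemical",
        "id": "@cas",
        "fields": {
            "name": "name",
            "synonyms": "synonym",  # repeated element, one synonym each
            "inchikey": "inchikey",
            "comptox": "comptox",
        },
    },
    "terms": {
        "cell": "cell-term",
        "organ": "organ-term",
        "taxonomy": "taxonomy",
        "process": "biological-process",
        "object": "biological-object",
        "action": "biological-action",
    },
}


def load_dialect(path: str | Path | None) -> dict:
    """Merge a user dialect mapping (YAML) over the fixture dialect."""
    import copy

    import yaml

    dialect = copy.deepcopy(DEFAULT_DIALECT)
    if path is None:
        return dialect
    with open(path, encoding="utf-8") as fh:
        override = yaml.safe_load(fh) or {}

    def merge(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    merge(dialect, override)
    return dialect


# ---------------------------------------------------------------------------
# path extraction helpers

_INT_FIELDS = {"ke_ids", "mie_ids", "ao_ids", "ker_ids", "stressor_ids",
               "upstream_ke", "downstream_ke"}
_DATE_FIELDS = {"created", "modified"}
_SPLIT_FIELDS = {"creators"}
_REPEATED_FIELDS = {"synonyms"}
_LIST_FIELDS = {"ke_ids", "mie_ids", "ao_ids", "ker_ids", "stressor_ids",
                "process_terms", "object_terms", "action_terms", "taxa",
                "chemical_cas"}


def _find_values(elem: etree._Element, path: str) -> list[str]:
    if path.startswith("@"):
        v = elem.get(path[1:])
        return [v] if v is not None else []
    if "@" in path:
        tag_path, attr = path.rsplit("@", 1)
        return [c.get(attr) for c in elem.findall(tag_path) if c.get(attr) is not None]
    out = []
    for c in elem.findall(path):
        if c.text is not None and c.text.strip():
            out.append(c.text.strip())
    return out


def _parse_timestamp(text: str, where: str, report: ParseReport) -> datetime | None:
    # ISO-8601 without timezone, matching the wiki's printed form
    try:
        return datetime.fromisoformat(text)
    except ValueError:
        report.warn(f"{where}: unparseable timestamp {text!r}, dropped")
        return None


# ---------------------------------------------------------------------------
# parsing


def parse_aopwiki_xml(
    path: str | Path,
    dialect: dict | str | Path | None = None,
) -> KnowledgeModel:
    """Parse an XML dump into a :class:`KnowledgeModel`.

    *dialect* may be a mapping (merged over the fixture dialect), a path to a
    YAML dialect file, or None for the fixture dialect. Unknown elements are
    ignored; entities missing mandatory fields (id, title) are skipped with a
    warning; dangling cross-references are recorded in ``model.report`` and
    the entries retained (except MIE/AO ids outside an AOP's KE list, which
    are dropped from that AOP).
    """
    if dialect is None or isinstance(dialect, (str, Path)):
        dialect = load_dialect(dialect)
    else:
        merged = load_dialect(None)

        def merge(dst: dict, src: dict) -> None:
            for k, v in src.items():
                if isinstance(v, dict) and isinstance(dst.get(k), dict):
                    merge(dst[k], v)
                else:
                    dst[k] = v

        merge(merged, dialect)
        dialect = merged

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    model = KnowledgeModel(source_path=str(path))
    report = model.report

    snap = dialect.get("snapshot_date", "@snapshot-date")
    if snap.startswith("@"):
        model.snapshot_date = root.get(snap[1:])

    delimiter = dialect.get("delimiter", "\n")

    _parse_terms(root, dialect, model)
    _parse_entities(root, dialect, "chemical", model, delimiter)
    _parse_entities(root, dialect, "stressor", model, delimiter)
    _parse_entities(root, dialect, "ke", model, delimiter)
    _parse_entities(root, dialect, "ker", model, delimiter)
    _parse_entities(root, dialect, "aop", model, delimiter)
    _check_references(model)
    return model


def _parse_terms(root: etree._Element, dialect: dict, model: KnowledgeModel) -> None:
    report = model.report
    for kind, tag in dialect["terms"].items():
        n_ok = n_skip = 0
        for elem in root.findall(tag):
            curie = elem.get("curie")
            free = elem.get("id")
            label = elem.get("label") or (elem.text.strip() if elem.text else "")
            if curie is None and free is None:
                report.warn(
                    f"line {elem.sourceline}: {kind} term without curie or id, skipped"
                )
                n_skip += 1
                continue
            if curie is not None and free is not None:
                report.warn(
                    f"line {elem.sourceline}: {kind} term {curie} has both curie "
                    "and free id; curie kept"
                )
                free = None
            term = TermEntry(kind=kind, label=label, curie=curie, free_text=free)
            if term.key in model.terms and model.terms[term.key].kind != kind:
                report.warn(
                    f"term {term.key} declared as both "
                    f"{model.terms[term.key].kind} and {kind}; first kept"
                )
                n_skip += 1
                continue
            model.terms[term.key] = term
            n_ok += 1
        report.parsed[f"{kind}_terms"] = n_ok
        if n_skip:
            report.skipped[f"{kind}_terms"] = n_skip


_ENTITY_CLS = {
    "aop": AopEntry,
    "ke": KeyEventEntry,
    "ker": KerEntry,
    "stressor": StressorEntry,
    "chemical": ChemicalEntry,
}
_COLLECTION = {
    "aop": "aops",
    "ke": "kes",
    "ker": "kers",
    "stressor": "stressors",
    "chemical": "chemicals",
}


def _parse_entities(
    root: etree._Element,
    dialect: dict,
    kind: str,
    model: KnowledgeModel,
    delimiter: str,
) -> None:
    report = model.report
    spec = dialect[kind]
    collection: dict = getattr(model, _COLLECTION[kind])
    n_ok = n_skip = 0
    for elem in root.findall(spec["tag"]):
        where = f"line {elem.sourceline}: {kind}"
        raw_id = _find_values(elem, spec["id"])
        if not raw_id:
            report.warn(f"{where} without id, skipped")
            n_skip += 1
            continue
        entity = _build_entity(kind, raw_id[0], elem, spec, delimiter, report)
        if entity is None:
            n_skip += 1
            continue
        key = entity.cas if kind == "chemical" else entity.id
        if key in collection:
            report.warn(f"{where} {key}: duplicate id, first occurrence kept")
            n_skip += 1
            continue
        collection[key] = entity
        n_ok += 1
    report.parsed[_COLLECTION[kind]] = n_ok
    if n_skip:
        report.skipped[_COLLECTION[kind]] = n_skip


def _build_entity(kind, raw_id, elem, spec, delimiter, report):
    where = f"line {elem.sourceline}: {kind} {raw_id}"
    values: dict = {}
    if kind == "chemical":
        if not CAS_RE.match(raw_id):
            report.warn(f"{where}: invalid CAS number, entity skipped")
            return None
        values["cas"] = raw_id
    else:
        try:
            ident = int(raw_id)
            if ident <= 0:
                raise ValueError
        except ValueError:
            report.warn(f"{where}: id must be a positive integer, skipped")
            return None
        values["id"] = ident

    for field_name, path in spec["fields"].items():
        found = _find_values(elem, path)
        if field_name in _SPLIT_FIELDS:
            parts: list[str] = []
            for v in found:
                parts.extend(p.strip() for p in v.split(delimiter) if p.strip())
            values[field_name] = parts
        elif field_name in _REPEATED_FIELDS:
            values[field_name] = found
        elif field_name in _LIST_FIELDS:
            if field_name in _INT_FIELDS:
                ints = []
                for v in found:
                    try:
                        ints.append(int(v))
                    except ValueError:
                        report.warn(f"{where}: non-integer reference {v!r} dropped")
                values[field_name] = ints
            else:
                values[field_name] = found
        elif found:
            v = found[0]
            if len(found) > 1:
                report.warn(f"{where}: multiple values for {field_name}, first kept")
            if field_name in _DATE_FIELDS:
                values[field_name] = _parse_timestamp(v, where, report)
            elif field_name in _INT_FIELDS:
                try:
                    values[field_name] = int(v)
                except ValueError:
                    report.warn(f"{where}: non-integer {field_name} {v!r}, skipped")
                    return None
            else:
                values[field_name] = v

    # mandatory / structural checks
    if kind in ("aop", "ke", "stressor") and not values.get("title"):
        report.warn(f"{where}: missing mandatory title, skipped")
        return None
    if kind == "chemical" and not values.get("name"):
        report.warn(f"{where}: missing mandatory name, skipped")
        return None
    if kind == "ker":
        up, down = values.get("upstream_ke"), values.get("downstream_ke")
        if up is None or down is None:
            report.warn(f"{where}: missing upstream/downstream key event, skipped")
            return None
        if up == down:
            report.warn(f"{where}: self-loop (upstream == downstream), skipped")
            return None
    if kind == "chemical":
        ik = values.get("inchikey")
        if ik is not None and not INCHIKEY_RE.match(ik):
            report.warn(f"{where}: malformed InChIKey {ik!r}, dropped")
            values["inchikey"] = None
    if kind == "stressor":
        kept = []
        for cas in values.get("chemical_cas", []):
            if CAS_RE.match(cas):
                kept.append(cas)
            else:
                report.warn(f"{where}: malformed CAS reference {cas!r}, dropped")
        values["chemical_cas"] = kept
    if kind == "aop":
        for sub, sup, label in (("mie_ids", "ke_ids", "MIE"), ("ao_ids", "ke_ids", "AO")):
            kes = set(values.get(sup, []))
            kept = [i for i in values.get(sub, []) if i in kes]
            for i in values.get(sub, []):
                if i not in kes:
                    report.warn(
                        f"{where}: {label} id {i} not in the AOP's key-event list, dropped"
                    )
            values[sub] = kept
    created, modified = values.get("created"), values.get("modified")
    if created and modified and created > modified:
        report.warn(f"{where}: created > modified")

    return _ENTITY_CLS[kind](**values)


def _check_references(model: KnowledgeModel) -> None:
    """Record every reference that does not resolve inside the model."""
    report = model.report

    def check(refs, defined, kind, where):
        for r in refs:
            if r not in defined:
                report.add_dangling(kind, str(r))
                report.warn(f"{where}: dangling {kind} reference {r}")

    for aop in model.aops.values():
        w = f"aop {aop.id}"
        check(aop.ke_ids, model.kes, "ke", w)
        check(aop.ker_ids, model.kers, "ker", w)
        check(aop.stressor_ids, model.stressors, "stressor", w)
    for ke in model.kes.values():
        w = f"ke {ke.id}"
        check(ke.stressor_ids, model.stressors, "stressor", w)
        for key in ([ke.cell_term] if ke.cell_term else []) + \
                   ([ke.organ_term] if ke.organ_term else []) + \
                   ke.process_terms + ke.object_terms + ke.action_terms + ke.taxa:
            if key not in model.terms:
                report.add_dangling("term", key)
                report.warn(f"{w}: dangling term reference {key}")
    for ker in model.kers.values():
        w = f"ker {ker.id}"
        check([ker.upstream_ke, ker.downstream_ke], model.kes, "ke", w)
        for key in ker.taxa:
            if key not in model.terms:
                report.add_dangling("term", key)
                report.warn(f"{w}: dangling term reference {key}")
    for s in model.stressors.values():
        check(s.chemical_cas, model.chemicals, "chemical", f"stressor {s.id}")


# ---------------------------------------------------------------------------
# reporting


def model_report(model: KnowledgeModel) -> str:
    """Deterministic text summary: per-collection counts plus dangling refs."""
    lines = []
    for name in ("aops", "kes", "kers", "stressors", "chemicals"):
        lines.append(f"{name}: {len(getattr(model, name))}")
    by_kind = {k: 0 for k in TERM_KINDS}
    for t in model.terms.values():
        by_kind[t.kind] += 1
    for kind in TERM_KINDS:
        lines.append(f"{kind}_terms: {by_kind[kind]}")
    dangling = model.report.dangling
    if dangling:
        lines.append("dangling references:")
        for kind in sorted(dangling):
            for ref in sorted(dangling[kind], key=str):
                lines.append(f"  {kind}: {ref}")
    else:
        lines.append("dangling references: none")
    if model.report.warnings:
        lines.append(f"warnings: {len(model.report.warnings)}")
    return "\n".join(lines)
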