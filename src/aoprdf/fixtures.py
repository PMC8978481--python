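"""Synthetic fixture generation: XML dumps plus companion tables with truth.

Two kinds of fixtures support testing every pipeline stage offline:

* :func:`generate_fixture` builds a seeded random wiki (AOPs with KE chains,
  KERs, stressors, chemicals, ontology terms) whose free-text fields contain
  *planted* gene symbols at recorded positions and *decoy* tokens (symbols
  embedded inside longer alphanumeric words, which boundary-aware matching
  must ignore). Because the truth object is recorded while planting, the
  end-to-end expectation is exact, not statistical.

* :func:`canonical_fixture` writes a small hand-written wiki whose records
  mirror well-known public entries (the protein-alkylation liver-fibrosis
  pathway AOP 38, the histone-deacetylase-inhibition key event KE 1502, the
  UROD relationship KER 865, the gemfibrozil stressor 208 and acetaminophen
  CAS 103-90-2), together with the exemplar triples a conversion of it must
  contain (:data:`CANONICAL_EXEMPLARS`).

The companion identifier tables (HGNC gene table, promapping-style PR table,
static cross-reference table) are synthetic: gene symbols and most identifier
values are real public nomenclature/database values to keep matching
realistic, but the tables themselves are constructed, not downloaded.
"""

from __future__ import annotations

import json
import random
import shutil
import string
from dataclasses import dataclass, field as dc_field, asdict
from importlib import resources
from pathlib import Path

from .xrefs import CHEMICAL_DBS, GENE_DBS

__all__ = [
    "FixtureConfig",
    "FixtureTruth",
    "FixtureBundle",
    "generate_fixture",
    "canonical_fixture",
    "Exemplar",
    "CANONICAL_EXEMPLARS",
    "mini_hgnc_path",
]

_WORDS = (
    "lorem ipsum dolor sit amet consectetur adipiscing elit sed do eiusmod "
    "tempor incididunt ut labore et dolore magna aliqua enim ad minim veniam "
    "quis nostrud exercitation ullamco laboris nisi aliquip ex ea commodo "
    "consequat duis aute irure reprehenderit voluptate velit esse cillum"
).split()

_CELL_TERMS = ("CL:0000000", "CL:0000182")
_ORGAN_TERMS = ("UBERON:0000062", "FMA:7197")
_PROCESS_TERMS = ("GO:0004857", "GO:0006915", "MI:0915", "MESH:D008107",
                  "HP:0000118", "MP:0001556", "PCO:0000001")
_OBJECT_TERMS = ("PR:000008478", "PR:000003035", "CHEBI:15846",
                 "VT:0000979", "NBO:0000313")
_ACTION_TERMS = ("WIKI:1", "WIKI:2")
_TAXA_TERMS = ("NCBITAXON:9606", "NCBITAXON:10090", "NCBITAXON:10116", "WCS_9606")

_TERM_LABELS = {
    "CL:0000000": "cell",
    "CL:0000182": "hepatocyte",
    "UBERON:0000062": "organ",
    "FMA:7197": "liver",
    "GO:0004857": "enzyme inhibitor activity",
    "GO:0006915": "apoptotic process",
    "MI:0915": "physical association",
    "MESH:D008107": "liver diseases",
    "HP:0000118": "phenotypic abnormality",
    "MP:0001556": "increased circulating bilirubin level",
    "PCO:0000001": "population of organisms",
    "PR:000008478": "histone deacetylase 9 (human)",
    "PR:000003035": "tumor protein p53 (human)",
    "CHEBI:15846": "NAD(+)",
    "VT:0000979": "liver physiology trait",
    "NBO:0000313": "feeding behavior",
    "WIKI:1": "increased",
    "WIKI:2": "decreased",
    "NCBITAXON:9606": "Homo sapiens",
    "NCBITAXON:10090": "Mus musculus",
    "NCBITAXON:10116": "Rattus norvegicus",
    "WCS_9606": "Homo sapiens (wiki taxon)",
}

# promapping-style rows for the PR object terms (synthetic table, real ids)
_PR_ROWS = (
    ("PR:000008478", "UniProtKB:Q9UKV0", "is_a"),
    ("PR:000008478", "HGNC:HDAC9", "is_a"),
    ("PR:000008478", "NCBIGene:9734", "is_a"),
    ("PR:000003035", "UniProtKB:P04637", "is_a"),
    ("PR:000003035", "HGNC:TP53", "is_a"),
    ("PR:000003035", "NCBIGene:7157", "is_a"),
)


def mini_hgnc_path() -> Path:
    """Path of the bundled 50-symbol gene nomenclature mini-table."""
    return Path(str(resources.files("aoprdf.data").joinpath("hgnc_mini.tsv")))


def _load_symbols() -> list[str]:
    lines = mini_hgnc_path().read_text().splitlines()[1:]
    return [ln.split("\t")[1] for ln in lines if ln.strip()]


# ---------------------------------------------------------------------------
# random fixture


@dataclass
class FixtureConfig:
    """Knobs of the random fixture; identical seed ⇒ byte-identical bundle."""

    n_aops: int = 3
    kes_per_aop: int = 4
    n_stressors: int = 4
    n_chemicals: int = 3
    chemical_fraction: float = 0.75     # stressors carrying a chemical
    genes_min: int = 0                  # planted symbols per scanned field
    genes_max: int = 3
    decoy_rate: float = 0.3             # chance of adding an embedded decoy
    xref_db_rate: float = 0.8           # chance each chemical DB has a mapping
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_aops, self.n_stressors, self.n_chemicals) < 0:
            raise ValueError("entity counts must be >= 0")
        if self.n_aops > 0 and self.kes_per_aop < 2:
            raise ValueError("each AOP needs at least an MIE and an AO "
                             "(kes_per_aop >= 2)")
        for name in ("chemical_fraction", "decoy_rate", "xref_db_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {v}")
        if not 0 <= self.genes_min <= self.genes_max:
            raise ValueError("need 0 <= genes_min <= genes_max")


@dataclass
class FixtureTruth:
    """Everything the pipeline must find, derived from config + seed alone."""

    counts: dict[str, int] = dc_field(default_factory=dict)
    matches: dict[str, dict[str, dict[str, list[str]]]] = dc_field(default_factory=dict)
    chemical_xrefs: dict[str, list[list[str]]] = dc_field(default_factory=dict)
    gene_xrefs: dict[str, list[list[str]]] = dc_field(default_factory=dict)
    pr_xrefs: dict[str, list[list[str]]] = dc_field(default_factory=dict)
    decoys: list[str] = dc_field(default_factory=list)

    def record_match(self, kind: str, entity_id: int, field_name: str, symbol: str) -> None:
        fields = self.matches.setdefault(kind, {}).setdefault(str(entity_id), {})
        forms = fields.setdefault(field_name, [])
        if symbol not in forms:
            forms.append(symbol)
            forms.sort()


@dataclass
class FixtureBundle:
    xml_path: Path
    hgnc_path: Path
    pr_path: Path
    xref_path: Path
    truth_path: Path | None
    truth: FixtureTruth | None


def _xml_escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


class _Xml:
    """Tiny deterministic XML writer (two-space indent)."""

    def __init__(self) -> None:
        self.lines: list[str] = ['<?xml version="1.0" encoding="UTF-8"?>']
        self.depth = 0

    def open(self, tag: str, **attrs) -> None:
        self.lines.append("  " * self.depth + self._start(tag, attrs) + ">")
        self.depth += 1

    def close(self, tag: str) -> None:
        self.depth -= 1
        self.lines.append("  " * self.depth + f"</{tag}>")

    def leaf(self, tag: str, text: str | None = None, **attrs) -> None:
        start = self._start(tag, attrs)
        if text is None:
            self.lines.append("  " * self.depth + start + "/>")
        else:
            self.lines.append(
                "  " * self.depth + start + ">" + _xml_escape(text) + f"</{tag}>"
            )

    @staticmethod
    def _start(tag: str, attrs: dict) -> str:
        parts = [f"<{tag}"]
        for k, v in attrs.items():
            if v is not None:
                parts.append(f' {k.replace("_", "-")}="{_xml_escape(str(v))}"')
        return "".join(parts)

    def text(self) -> str:
        return "\n".join(self.lines) + "\n"


def _random_cas(rng: random.Random, taken: set[str]) -> str:
    while True:
        cas = f"{rng.randint(10, 9999999)}-{rng.randint(10, 99)}-{rng.randint(0, 9)}"
        if cas not in taken:
            taken.add(cas)
            return cas


def _random_inchikey(rng: random.Random) -> str:
    letters = string.ascii_uppercase
    return (
        "".join(rng.choice(letters) for _ in range(14))
        + "-" + "".join(rng.choice(letters) for _ in range(10))
        + "-" + rng.choice(letters)
    )


def _sentence(rng: random.Random, n_words: int) -> list[str]:
    return [rng.choice(_WORDS) for _ in range(n_words)]


def _planted_text(
    rng: random.Random,
    symbols: list[str],
    truth: FixtureTruth,
    kind: str,
    entity_id: int,
    field_name: str,
    config: FixtureConfig,
) -> str:
    """Random filler text with planted gene symbols and optional decoys."""
    tokens = _sentence(rng, rng.randint(6, 14))
    n_genes = rng.randint(config.genes_min, config.genes_max)
    for sym in rng.sample(symbols, n_genes):
        tokens.insert(rng.randint(0, len(tokens)), sym)
        truth.record_match(kind, entity_id, field_name, sym)
    if rng.random() < config.decoy_rate:
        decoy = "x" + rng.choice(symbols) + "z"  # embedded: no boundaries
        tokens.insert(rng.randint(0, len(tokens)), decoy)
        truth.decoys.append(decoy)
    return " ".join(tokens) + "."


def generate_fixture(config: FixtureConfig, outdir: str | Path) -> FixtureBundle:
    """Write a seeded random fixture bundle (XML + three tables + truth JSON)."""
    config.validate()
    rng = random.Random(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    symbols = _load_symbols()
    truth = FixtureTruth()

    taken: set[str] = set()
    chemicals = []
    for i in range(config.n_chemicals):
        chemicals.append({
            "cas": _random_cas(rng, taken),
            "name": f"compound {i + 1}",
            "synonyms": [f"compound-{i + 1}-synonym"],
            "inchikey": _random_inchikey(rng),
            "comptox": f"DTXSID{rng.randint(1000000, 9999999)}",
        })

    stressors = []
    for i in range(config.n_stressors):
        has_chem = chemicals and (i / max(config.n_stressors, 1)) < config.chemical_fraction
        stressors.append({
            "id": i + 1,
            "title": f"stressor {i + 1}",
            "cas": chemicals[i % len(chemicals)]["cas"] if has_chem else None,
        })

    next_ke, next_ker = 1, 1
    aops, kes, kers = [], [], []
    for a in range(1, config.n_aops + 1):
        ke_ids = list(range(next_ke, next_ke + config.kes_per_aop))
        next_ke += config.kes_per_aop
        stressor_id = stressors[(a - 1) % len(stressors)]["id"] if stressors else None
        for idx, ke_id in enumerate(ke_ids):
            ke = {
                "id": ke_id,
                "title": f"key event {ke_id}",
                "bio_level": rng.choice(("Molecular", "Cellular", "Tissue", "Organ")),
                "description": _planted_text(
                    rng, symbols, truth, "ke", ke_id, "ke_description", config),
                "cell": rng.choice(_CELL_TERMS),
                "organ": rng.choice(_ORGAN_TERMS),
                "process": rng.choice(_PROCESS_TERMS),
                "object": rng.choice(_OBJECT_TERMS),
                "action": rng.choice(_ACTION_TERMS),
                "taxon": rng.choice(_TAXA_TERMS),
                "stressor": stressor_id if idx == 0 else None,  # MIE only
                "mie_ao_section": None,
            }
            if rng.random() < 0.5:
                ke["mie_ao_section"] = _planted_text(
                    rng, symbols, truth, "ke", ke_id, "mie_ao_section", config)
            kes.append(ke)
        ker_ids = []
        for up, down in zip(ke_ids, ke_ids[1:]):
            kers.append({
                "id": next_ker,
                "up": up,
                "down": down,
                "description": _planted_text(
                    rng, symbols, truth, "ker", next_ker, "ker_description", config),
                "plausibility": _planted_text(
                    rng, symbols, truth, "ker", next_ker, "biological_plausibility",
                    config),
                "empirical": _planted_text(
                    rng, symbols, truth, "ker", next_ker, "empirical_support", config),
            })
            ker_ids.append(next_ker)
            next_ker += 1
        aops.append({
            "id": a,
            "title": f"pathway {a}",
            "ke_ids": ke_ids,
            "mie_ids": [ke_ids[0]],
            "ao_ids": [ke_ids[-1]],
            "ker_ids": ker_ids,
            "stressor_ids": [stressor_id] if stressor_id else [],
        })

    # --- XML ---------------------------------------------------------------
    x = _Xml()
    x.open("data", snapshot_date="2021-01-01")
    used_terms: dict[str, str] = {}

    def use(kind: str, key: str | None) -> None:
        if key is not None:
            used_terms[key] = kind

    for aop in aops:
        x.open("aop", id=aop["id"])
        x.leaf("title", aop["title"])
        x.leaf("creators", "fixture author")
        x.leaf("status", "Under development")
        x.leaf("created", "2020-01-01T00:00:00")
        x.leaf("modified", "2021-01-01T00:00:00")
        x.open("key-events")
        for k in aop["ke_ids"]:
            x.leaf("key-event", ref=k)
        x.close("key-events")
        x.open("molecular-initiating-events")
        for k in aop["mie_ids"]:
            x.leaf("key-event", ref=k)
        x.close("molecular-initiating-events")
        x.open("adverse-outcomes")
        for k in aop["ao_ids"]:
            x.leaf("key-event", ref=k)
        x.close("adverse-outcomes")
        x.open("key-event-relationships")
        for k in aop["ker_ids"]:
            x.leaf("key-event-relationship", ref=k)
        x.close("key-event-relationships")
        if aop["stressor_ids"]:
            x.open("stressors")
            for s in aop["stressor_ids"]:
                x.leaf("stressor", ref=s)
            x.close("stressors")
        x.close("aop")
    for ke in kes:
        x.open("key-event", id=ke["id"])
        x.leaf("title", ke["title"])
        x.leaf("bio-level", ke["bio_level"])
        x.leaf("description", ke["description"])
        if ke["mie_ao_section"]:
            x.leaf("mie-ao-section", ke["mie_ao_section"])
        for tag, key in (("cell-term", "cell"), ("organ-term", "organ"),
                         ("biological-process", "process"),
                         ("biological-object", "object"),
                         ("biological-action", "action"),
                         ("taxonomy", "taxon")):
            x.leaf(tag, ref=ke[key])
            use({"cell-term": "cell", "organ-term": "organ",
                 "biological-process": "process", "biological-object": "object",
                 "biological-action": "action", "taxonomy": "taxonomy"}[tag],
                ke[key])
        if ke["stressor"]:
            x.leaf("stressor", ref=ke["stressor"])
        x.close("key-event")
    for ker in kers:
        x.open("key-event-relationship", id=ker["id"])
        x.leaf("upstream", ref=ker["up"])
        x.leaf("downstream", ref=ker["down"])
        x.leaf("description", ker["description"])
        x.leaf("biological-plausibility", ker["plausibility"])
        x.leaf("empirical-support", ker["empirical"])
        x.close("key-event-relationship")
    for s in stressors:
        x.open("stressor", id=s["id"])
        x.leaf("title", s["title"])
        if s["cas"]:
            x.leaf("chemical-ref", cas=s["cas"])
        x.close("stressor")
    for c in chemicals:
        x.open("chemical", cas=c["cas"])
        x.leaf("name", c["name"])
        for syn in c["synonyms"]:
            x.leaf("synonym", syn)
        x.leaf("inchikey", c["inchikey"])
        x.leaf("comptox", c["comptox"])
        x.close("chemical")
    for key in sorted(used_terms):
        kind = used_terms[key]
        tag = {"cell": "cell-term", "organ": "organ-term", "taxonomy": "taxonomy",
               "process": "biological-process", "object": "biological-object",
               "action": "biological-action"}[kind]
        label = _TERM_LABELS.get(key, key)
        if ":" in key and not key.startswith("WIKI"):
            x.leaf(tag, curie=key, label=label)
        else:
            x.leaf(tag, id=key, label=label)
    x.close("data")

    xml_path = outdir / "fixture.xml"
    xml_path.write_text(x.text(), encoding="utf-8")

    # --- companion tables --------------------------------------------------
    hgnc_path = outdir / "hgnc.tsv"
    shutil.copyfile(mini_hgnc_path(), hgnc_path)

    pr_path = outdir / "promapping.tsv"
    pr_lines = ["# synthetic promapping-style table: PR id, target CURIE, relation"]
    for pr_id, target, rel in _PR_ROWS:
        if pr_id in used_terms:
            pr_lines.append(f"{pr_id}\t{target}\t{rel}")
            db, local = _pr_target(target)
            truth.pr_xrefs.setdefault(pr_id, []).append([db, local])
    pr_path.write_text("\n".join(pr_lines) + "\n", encoding="utf-8")

    xref_path = outdir / "xrefs.tsv"
    xref_lines = ["# synthetic cross-reference table: source_db, source_id, target_db, target_id"]
    for c in chemicals:
        for db in sorted(CHEMICAL_DBS):
            if rng.random() < config.xref_db_rate:
                target_id = f"X{rng.randint(10000, 99999)}"
                xref_lines.append(f"cas\t{c['cas']}\t{db}\t{target_id}")
                truth.chemical_xrefs.setdefault(c["cas"], []).append([db, target_id])
    planted = sorted({
        sym
        for by_id in truth.matches.values()
        for by_field in by_id.values()
        for syms in by_field.values()
        for sym in syms
    })
    for sym in planted:
        for db in sorted(GENE_DBS):
            target_id = f"G{abs(hash((sym, db, config.seed))) % 10 ** 6}"
            xref_lines.append(f"hgnc\t{sym}\t{db}\t{target_id}")
            truth.gene_xrefs.setdefault(sym, []).append([db, target_id])
    xref_path.write_text("\n".join(xref_lines) + "\n", encoding="utf-8")

    truth.counts = {
        "aops": len(aops),
        "kes": len(kes),
        "kers": len(kers),
        "stressors": len(stressors),
        "chemicals": len(chemicals),
        "terms": len(used_terms),
    }
    # gene-link triples: one per (entity, distinct symbol)
    truth.counts["gene_link_triples"] = sum(
        len({sym for syms in fields.values() for sym in syms})
        for kind_map in truth.matches.values()
        for fields in kind_map.values()
    )

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(asdict(truth), indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
    return FixtureBundle(xml_path, hgnc_path, pr_path, xref_path, truth_path, truth)


def _pr_target(target: str) -> tuple[str, str]:
    prefix, local = target.split(":", 1)
    return {"UniProtKB": "uniprot", "HGNC": "hgnc", "NCBIGene": "ncbigene"}[prefix], local


# ---------------------------------------------------------------------------
# canonical fixture

_CANONICAL_XML = """<?xml version="1.0" encoding="UTF-8"?>
<data snapshot-date="2021-01-01">
  <aop id="38">
    <title>Protein Alkylation leading to Liver Fibrosis</title>
    <alternative-title>Protein Alkylation to Liver Fibrosis</alternative-title>
    <creators>Brigitte Landesmann</creators>
    <abstract>Hepatotoxicity in general is of special interest for human health risk assessment.</abstract>
    <description>Two prototypical chemicals acting via protein alkylation are allyl alcohol and carbon tetrachloride.</description>
    <status>Open for citation &amp; comment</status>
    <created>2016-11-29T18:41:16</created>
    <modified>2019-04-30T12:53:51</modified>
    <sex-applicability>Unspecific</sex-applicability>
    <life-stage>Not Otherwise Specified</life-stage>
    <applicability>The described AOP is valid for both sexes and any life stage of the organisms considered.</applicability>
    <quantitative-considerations>More advanced in vitro models systems are needed for quantitative extrapolation.</quantitative-considerations>
    <weight-of-evidence>Support for Essentiality of KEs within this pathway is strong.</weight-of-evidence>
    <potential-applications>This systematic and coherent display of currently available mechanistic information supports read-across.</potential-applications>
    <overall-assessment>Assessment of the Weight-of-Evidence supporting the AOP is summarised here.</overall-assessment>
    <ke-essentiality>The essentiality of each of the KEs for this AOP was rated high.</ke-essentiality>
    <key-events>
      <key-event ref="55"/>
      <key-event ref="244"/>
      <key-event ref="344"/>
      <key-event ref="1492"/>
      <key-event ref="1493"/>
    </key-events>
    <molecular-initiating-events>
      <key-event ref="244"/>
    </molecular-initiating-events>
    <adverse-outcomes>
      <key-event ref="344"/>
    </adverse-outcomes>
    <key-event-relationships>
      <key-event-relationship ref="269"/>
      <key-event-relationship ref="1718"/>
    </key-event-relationships>
    <stressors>
      <stressor ref="9"/>
      <stressor ref="13"/>
      <stressor ref="60"/>
    </stressors>
  </aop>
  <aop id="18">
    <title>Peroxisome proliferation stub pathway</title>
    <key-events>
      <key-event ref="227"/>
      <key-event ref="1170"/>
    </key-events>
    <molecular-initiating-events>
      <key-event ref="227"/>
    </molecular-initiating-events>
    <stressors>
      <stressor ref="208"/>
    </stressors>
  </aop>
  <aop id="37">
    <title>Stub pathway thirty-seven</title>
    <stressors><stressor ref="208"/></stressors>
  </aop>
  <aop id="51">
    <title>Stub pathway fifty-one</title>
    <stressors><stressor ref="208"/></stressors>
  </aop>
  <aop id="61">
    <title>Stub pathway sixty-one</title>
    <stressors><stressor ref="208"/></stressors>
  </aop>
  <aop id="323">
    <title>Stub pathway three-two-three</title>
    <stressors><stressor ref="208"/></stressors>
  </aop>
  <aop id="131">
    <title>Uroporphyria pathway</title>
    <key-events>
      <key-event ref="844"/>
      <key-event ref="845"/>
    </key-events>
    <molecular-initiating-events><key-event ref="844"/></molecular-initiating-events>
    <adverse-outcomes><key-event ref="845"/></adverse-outcomes>
    <key-event-relationships><key-event-relationship ref="865"/></key-event-relationships>
  </aop>
  <aop id="212">
    <title>Histone modification stub pathway</title>
    <key-events>
      <key-event ref="1502"/>
      <key-event ref="1503"/>
    </key-events>
    <molecular-initiating-events><key-event ref="1502"/></molecular-initiating-events>
    <adverse-outcomes><key-event ref="1503"/></adverse-outcomes>
  </aop>
  <aop id="274">
    <title>Chromatin stub pathway two-seven-four</title>
    <key-events><key-event ref="1502"/></key-events>
  </aop>
  <aop id="275">
    <title>Chromatin stub pathway two-seven-five</title>
    <key-events><key-event ref="1502"/></key-events>
  </aop>
  <key-event id="55"><title>Hepatocyte injury stub</title></key-event>
  <key-event id="244">
    <title>Protein alkylation initiating event</title>
    <stressor ref="9"/>
  </key-event>
  <key-event id="344"><title>Liver fibrosis outcome</title></key-event>
  <key-event id="1492"><title>Stellate cell activation stub</title></key-event>
  <key-event id="1493"><title>Collagen accumulation stub</title></key-event>
  <key-event id="227">
    <title>Receptor activation stub</title>
    <stressor ref="208"/>
  </key-event>
  <key-event id="1170">
    <title>Lipid accumulation stub</title>
    <stressor ref="208"/>
  </key-event>
  <key-event id="844">
    <title>Uroporphyrinogen decarboxylase inhibition</title>
    <description>Strong depression of hepatic decarboxylase activity.</description>
  </key-event>
  <key-event id="845">
    <title>Accumulation of highly carboxylated porphyrins</title>
  </key-event>
  <key-event id="1502">
    <title>Histone deacetylase inhibition</title>
    <alternative-title>Histone deacetylase inhibition</alternative-title>
    <bio-level>Molecular</bio-level>
    <description>The inhibition of HDAC by HDIs is well conserved across species; HDAC9, MAA, and PRDX2 serve as readouts.</description>
    <measurement-method>The measurement of HDAC inhibition monitors changes in acetylation state.</measurement-method>
    <cell-term ref="CL:0000000"/>
    <organ-term ref="UBERON:0000062"/>
    <biological-process ref="GO:0004857"/>
    <biological-object ref="PR:000008478"/>
    <biological-action ref="WIKI:2"/>
    <taxonomy ref="NCBITAXON:10116"/>
    <taxonomy ref="WCS_9606"/>
    <taxonomy ref="NCBITAXON:10090"/>
    <stressor ref="340"/>
    <stressor ref="341"/>
    <stressor ref="342"/>
    <sex-applicability>Unspecific</sex-applicability>
    <life-stage>All life stages</life-stage>
  </key-event>
  <key-event id="1503">
    <title>Hepatocyte death breadth probe</title>
    <bio-level>Cellular</bio-level>
    <description>Executioner protease activation commits hepatocytes to programmed death.</description>
    <cell-term ref="CL:0000182"/>
    <organ-term ref="FMA:7197"/>
    <biological-process ref="MI:0915"/>
    <biological-process ref="MESH:D008107"/>
    <biological-process ref="HP:0000118"/>
    <biological-process ref="MP:0001556"/>
    <biological-process ref="PCO:0000001"/>
    <biological-object ref="CHEBI:15846"/>
    <biological-object ref="VT:0000979"/>
    <biological-object ref="NBO:0000313"/>
    <biological-action ref="WIKI:1"/>
    <taxonomy ref="NCBITAXON:9606"/>
  </key-event>
  <key-event-relationship id="269">
    <upstream ref="244"/>
    <downstream ref="55"/>
  </key-event-relationship>
  <key-event-relationship id="1718">
    <upstream ref="1493"/>
    <downstream ref="344"/>
  </key-event-relationship>
  <key-event-relationship id="865">
    <upstream ref="844"/>
    <downstream ref="845"/>
    <description>One of the oxidation products of uroporphyrinogen is a potent inhibitor of the decarboxylation step.</description>
    <biological-plausibility>Reduced UROD enzyme activity, not protein levels, is the proximate cause of porphyrin accumulation.</biological-plausibility>
    <empirical-support>Include consideration of temporal concordance and dose-response concordance across taxa.</empirical-support>
    <uncertainties>The precise mechanism of UROD inhibition has yet to be resolved.</uncertainties>
    <taxonomy ref="NCBITAXON:10090"/>
    <taxonomy ref="NCBITAXON:10116"/>
    <taxonomy ref="WCS_9606"/>
    <sex-applicability>Unspecific</sex-applicability>
    <life-stage>All life stages</life-stage>
    <created>2016-11-29T18:41:35</created>
    <modified>2018-05-30T10:58:18</modified>
  </key-event-relationship>
  <stressor id="9"><title>Allyl alcohol</title></stressor>
  <stressor id="13"><title>Carbon tetrachloride</title></stressor>
  <stressor id="60"><title>Thioacetamide</title></stressor>
  <stressor id="340"><title>Valproic acid stub</title></stressor>
  <stressor id="341"><title>Trichostatin stub</title></stressor>
  <stressor id="342"><title>Butyrate stub</title></stressor>
  <stressor id="208">
    <title>Gemfibrozil</title>
    <description>Fibrate drug</description>
    <chemical-ref cas="25812-30-0"/>
    <created>2016-11-29T18:42:27</created>
    <modified>2020-03-31T10:24:40</modified>
  </stressor>
  <stressor id="57">
    <title>Acetaminophen</title>
    <chemical-ref cas="103-90-2"/>
  </stressor>
  <chemical cas="103-90-2">
    <name>Acetaminophen</name>
    <synonym>4-Acetamidophenol</synonym>
    <synonym>Paracetamol</synonym>
    <inchikey>RZVAJINKPMORJF-UHFFFAOYSA-N</inchikey>
    <comptox>DTXSID2020006</comptox>
  </chemical>
  <chemical cas="25812-30-0">
    <name>Gemfibrozil</name>
    <inchikey>HEMJJKBWTPKOJG-UHFFFAOYSA-N</inchikey>
  </chemical>
  <cell-term curie="CL:0000000" label="cell"/>
  <cell-term curie="CL:0000182" label="hepatocyte"/>
  <organ-term curie="UBERON:0000062" label="organ"/>
  <organ-term curie="FMA:7197" label="liver"/>
  <taxonomy curie="NCBITAXON:9606" label="Homo sapiens"/>
  <taxonomy curie="NCBITAXON:10090" label="Mus musculus"/>
  <taxonomy curie="NCBITAXON:10116" label="Rattus norvegicus"/>
  <taxonomy id="WCS_9606" label="Homo sapiens (wiki taxon)"/>
  <biological-process curie="GO:0004857" label="enzyme inhibitor activity"/>
  <biological-process curie="MI:0915" label="physical association"/>
  <biological-process curie="MESH:D008107" label="liver diseases"/>
  <biological-process curie="HP:0000118" label="phenotypic abnormality"/>
  <biological-process curie="MP:0001556" label="increased circulating bilirubin level"/>
  <biological-process curie="PCO:0000001" label="population of organisms"/>
  <biological-object curie="PR:000008478" label="histone deacetylase 9 (human)"/>
  <biological-object curie="CHEBI:15846" label="NAD(+)"/>
  <biological-object curie="VT:0000979" label="liver physiology trait"/>
  <biological-object curie="NBO:0000313" label="feeding behavior"/>
  <biological-action id="WIKI:1" label="increased"/>
  <biological-action id="WIKI:2" label="decreased"/>
</data>
"""

# cross-reference rows for the canonical bundle (synthetic table; identifier
# values are real database entries where the database covers the compound)
_CANONICAL_XREFS = (
    ("cas", "103-90-2", "chebi", "46195"),
    ("cas", "103-90-2", "chemspider", "1906"),
    ("cas", "103-90-2", "wikidata", "Q57055"),
    ("cas", "103-90-2", "chembl.compound", "CHEMBL112"),
    ("cas", "103-90-2", "pubchem.compound", "1983"),
    ("cas", "103-90-2", "drugbank", "DB00316"),
    ("cas", "103-90-2", "kegg.compound", "C06804"),
    ("cas", "103-90-2", "lipidmaps", "LMSYN000001"),
    ("cas", "103-90-2", "hmdb", "HMDB0001859"),
    ("cas", "25812-30-0", "chebi", "5296"),
    ("cas", "25812-30-0", "wikidata", "Q417725"),
    ("cas", "25812-30-0", "pubchem.compound", "3463"),
    ("hgnc", "UROD", "ncbigene", "7389"),
    ("hgnc", "UROD", "uniprot", "P06132"),
    ("hgnc", "UROD", "ensembl", "ENSG00000126088"),
    ("hgnc", "HDAC9", "ncbigene", "9734"),
    ("hgnc", "HDAC9", "uniprot", "Q9UKV0"),
    ("hgnc", "HDAC9", "ensembl", "ENSG00000048052"),
    ("hgnc", "PRDX2", "ncbigene", "7001"),
    ("hgnc", "PRDX2", "uniprot", "P32119"),
    ("hgnc", "PRDX2", "ensembl", "ENSG00000167815"),
    ("hgnc", "MAA", "ncbigene", "999101"),
    ("hgnc", "MAA", "uniprot", "Q9MAA0"),
    ("hgnc", "MAA", "ensembl", "ENSG00000999101"),
)

_CANONICAL_PR_ROWS = (
    ("PR:000008478", "UniProtKB:Q9UKV0", "is_a"),
    ("PR:000008478", "HGNC:HDAC9", "is_a"),
    ("PR:000008478", "NCBIGene:9734", "is_a"),
)


def canonical_fixture(outdir: str | Path) -> FixtureBundle:
    """Write the hand-written canonical bundle into *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    xml_path = outdir / "canonical.xml"
    xml_path.write_text(_CANONICAL_XML, encoding="utf-8")
    hgnc_path = outdir / "hgnc.tsv"
    shutil.copyfile(mini_hgnc_path(), hgnc_path)
    pr_path = outdir / "promapping.tsv"
    pr_path.write_text(
        "\n".join("\t".join(r) for r in _CANONICAL_PR_ROWS) + "\n", encoding="utf-8"
    )
    xref_path = outdir / "xrefs.tsv"
    xref_path.write_text(
        "\n".join("\t".join(r) for r in _CANONICAL_XREFS) + "\n", encoding="utf-8"
    )
    return FixtureBundle(xml_path, hgnc_path, pr_path, xref_path, None, None)


@dataclass(frozen=True)
class Exemplar:
    """One expected triple of the canonical conversion.

    ``kind`` is "iri" (value is a CURIE), "literal" or "typed" (value plus
    ``datatype`` CURIE); ``mode`` "prefix" accepts any literal starting with
    the given text (used where the reference rendering is truncated)."""

    graph: str        # "main" | "genes"
    subject: str      # CURIE
    predicate: str    # CURIE
    kind: str         # iri | literal | typed
    value: str
    mode: str = "exact"
    datatype: str | None = None


def _x(subject, predicate, kind, value, mode="exact", datatype=None, graph="main"):
    return Exemplar(graph, subject, predicate, kind, value, mode, datatype)


CANONICAL_EXEMPLARS: tuple[Exemplar, ...] = (
    # --- adverse outcome pathway 38 ---------------------------------------
    _x("aop:38", "rdf:type", "iri", "aopo:AdverseOutcomePathway"),
    _x("aop:38", "dc:identifier", "iri", "aop:38"),
    _x("aop:38", "rdfs:label", "literal", "AOP 38"),
    _x("aop:38", "dc:title", "literal", "Protein Alkylation leading to Liver Fibrosis"),
    _x("aop:38", "dcterms:alternative", "literal", "Protein Alkylation to Liver Fibrosis"),
    _x("aop:38", "dc:creator", "literal", "Brigitte Landesmann"),
    _x("aop:38", "dcterms:abstract", "literal",
       "Hepatotoxicity in general is of special interest", "prefix"),
    _x("aop:38", "nci:C54571", "iri", "aop.stressor:9"),
    _x("aop:38", "nci:C54571", "iri", "aop.stressor:13"),
    _x("aop:38", "nci:C54571", "iri", "aop.stressor:60"),
    _x("aop:38", "aopo:has_key_event", "iri", "aop.events:55"),
    _x("aop:38", "aopo:has_key_event", "iri", "aop.events:1492"),
    _x("aop:38", "aopo:has_key_event", "iri", "aop.events:1493"),
    _x("aop:38", "aopo:has_molecular_initiating_event", "iri", "aop.events:244"),
    _x("aop:38", "aopo:has_adverse_outcome", "iri", "aop.events:344"),
    _x("aop:38", "aopo:has_key_event_relationship", "iri", "aop.relationships:269"),
    _x("aop:38", "aopo:has_key_event_relationship", "iri", "aop.relationships:1718"),
    _x("aop:38", "dc:description", "literal",
       "Two prototypical chemicals acting via protein alkylation are", "prefix"),
    _x("aop:38", "pato:0000047", "literal", "Unspecific"),
    _x("aop:38", "aopo:LifeStageContext", "literal", "Not Otherwise Specified"),
    _x("aop:38", "aopo:AopContext", "literal",
       "The described AOP is valid for both sexes and any life stage", "prefix"),
    _x("aop:38", "edam:operation_3799", "literal",
       "More advanced in vitro models systems are needed", "prefix"),
    _x("aop:38", "aopo:has_evidence", "literal",
       "Support for Essentiality of KEs", "prefix"),
    _x("aop:38", "nci:C25725", "literal",
       "This systematic and coherent display of currently available", "prefix"),
    _x("aop:38", "nci:C25217", "literal",
       "Assessment of the Weight-of-Evidence supporting the AOP", "prefix"),
    _x("aop:38", "nci:C48192", "literal",
       "The essentiality of each of the KEs for this AOP", "prefix"),
    _x("aop:38", "dc:accessRights", "literal", "Open for citation & comment"),
    _x("aop:38", "foaf:page", "iri", "aop:38"),
    _x("aop:38", "dcterms:created", "typed", "2016-11-29T18:41:16",
       datatype="xsd:dateTime"),
    _x("aop:38", "dcterms:modified", "typed", "2019-04-30T12:53:51",
       datatype="xsd:dateTime"),
    _x("aop:38", "dc:source", "literal", "AOPWiki"),
    # --- key event 1502 ----------------------------------------------------
    _x("aop.events:1502", "rdf:type", "iri", "aopo:KeyEvent"),
    _x("aop.events:1502", "dc:identifier", "iri", "aop.events:1502"),
    _x("aop.events:1502", "rdfs:label", "literal", "KE 1502"),
    _x("aop.events:1502", "dc:title", "literal", "Histone deacetylase inhibition"),
    _x("aop.events:1502", "dcterms:alternative", "literal",
       "Histone deacetylase inhibition"),
    _x("aop.events:1502", "nci:C25664", "literal", "Molecular"),
    _x("aop.events:1502", "dc:description", "literal",
       "The inhibition of HDAC by HDIs is well conserved", "prefix"),
    _x("aop.events:1502", "mmo:0000000", "literal",
       "The measurement of HDAC inhibition monitors changes", "prefix"),
    _x("aop.events:1502", "nci:C54571", "iri", "aop.stressor:340"),
    _x("aop.events:1502", "nci:C54571", "iri", "aop.stressor:341"),
    _x("aop.events:1502", "nci:C54571", "iri", "aop.stressor:342"),
    _x("aop.events:1502", "aopo:CellTypeContext", "iri", "cl:0000000"),
    _x("aop.events:1502", "aopo:OrganContext", "iri", "uberon:0000062"),
    _x("aop.events:1502", "go:0008150", "iri", "go:0004857"),
    _x("aop.events:1502", "pato:0001241", "iri", "pr:000008478"),
    _x("aop.events:1502", "pato:0000001", "literal", "WIKI:2"),
    _x("aop.events:1502", "ncbitaxon:131567", "iri", "ncbitaxon:10116"),
    _x("aop.events:1502", "ncbitaxon:131567", "literal", "WCS_9606"),
    _x("aop.events:1502", "ncbitaxon:131567", "iri", "ncbitaxon:10090"),
    _x("aop.events:1502", "pato:0000047", "literal", "Unspecific"),
    _x("aop.events:1502", "aopo:LifeStageContext", "literal", "All life stages"),
    _x("aop.events:1502", "foaf:page", "iri", "aop.events:1502"),
    _x("aop.events:1502", "dcterms:isPartOf", "iri", "aop:212"),
    _x("aop.events:1502", "dcterms:isPartOf", "iri", "aop:274"),
    _x("aop.events:1502", "dcterms:isPartOf", "iri", "aop:275"),
    _x("aop.events:1502", "dc:source", "literal", "AOPWiki"),
    _x("aop.events:1502", "edam:data_1025", "iri", "hgnc:HDAC9", graph="genes"),
    _x("aop.events:1502", "edam:data_1025", "iri", "hgnc:MAA", graph="genes"),
    _x("aop.events:1502", "edam:data_1025", "iri", "hgnc:PRDX2", graph="genes"),
    # --- key event relationship 865 ----------------------------------------
    _x("aop.relationships:865", "rdf:type", "iri", "aopo:KeyEventRelationship"),
    _x("aop.relationships:865", "dc:identifier", "iri", "aop.relationships:865"),
    _x("aop.relationships:865", "rdfs:label", "literal", "KER 865"),
    _x("aop.relationships:865", "aopo:has_upstream_key_event", "iri", "aop.events:844"),
    _x("aop.relationships:865", "aopo:has_downstream_key_event", "iri", "aop.events:845"),
    _x("aop.relationships:865", "dc:description", "literal",
       "One of the oxidation products of uroporphyrinogen", "prefix"),
    _x("aop.relationships:865", "nci:C80263", "literal",
       "Reduced UROD enzyme activity, not protein levels", "prefix"),
    _x("aop.relationships:865", "edam:data_2042", "literal",
       "Include consideration of temporal concordance", "prefix"),
    _x("aop.relationships:865", "nci:C71478", "literal",
       "The precise mechanism of UROD inhibition has yet", "prefix"),
    _x("aop.relationships:865", "ncbitaxon:131567", "iri", "ncbitaxon:10090"),
    _x("aop.relationships:865", "ncbitaxon:131567", "iri", "ncbitaxon:10116"),
    _x("aop.relationships:865", "ncbitaxon:131567", "literal", "WCS_9606"),
    _x("aop.relationships:865", "pato:0000047", "literal", "Unspecific"),
    _x("aop.relationships:865", "aopo:LifeStageContext", "literal", "All life stages"),
    _x("aop.relationships:865", "foaf:page", "iri", "aop.relationships:865"),
    _x("aop.relationships:865", "dcterms:created", "typed", "2016-11-29T18:41:35",
       datatype="xsd:dateTime"),
    _x("aop.relationships:865", "dcterms:modified", "typed", "2018-05-30T10:58:18",
       datatype="xsd:dateTime"),
    _x("aop.relationships:865", "dcterms:isPartOf", "iri", "aop:131"),
    _x("aop.relationships:865", "edam:data_1025", "iri", "hgnc:UROD", graph="genes"),
    # --- stressor 208 -------------------------------------------------------
    _x("aop.stressor:208", "rdf:type", "iri", "nci:C54571"),
    _x("aop.stressor:208", "dc:identifier", "iri", "aop.stressor:208"),
    _x("aop.stressor:208", "rdfs:label", "literal", "Stressor 208"),
    _x("aop.stressor:208", "dc:title", "literal", "Gemfibrozil"),
    _x("aop.stressor:208", "dc:description", "literal", "Fibrate drug"),
    _x("aop.stressor:208", "aopo:has_chemical_entity", "iri", "cas:25812-30-0"),
    _x("aop.stressor:208", "foaf:page", "iri", "aop.stressor:208"),
    _x("aop.stressor:208", "dcterms:created", "typed", "2016-11-29T18:42:27",
       datatype="xsd:dateTime"),
    _x("aop.stressor:208", "dcterms:modified", "typed", "2020-03-31T10:24:40",
       datatype="xsd:dateTime"),
    _x("aop.stressor:208", "dcterms:isPartOf", "iri", "aop.events:227"),
    _x("aop.stressor:208", "dcterms:isPartOf", "iri", "aop.events:1170"),
    _x("aop.stressor:208", "dcterms:isPartOf", "iri", "aop:18"),
    _x("aop.stressor:208", "dcterms:isPartOf", "iri", "aop:37"),
    _x("aop.stressor:208", "dcterms:isPartOf", "iri", "aop:51"),
    _x("aop.stressor:208", "dcterms:isPartOf", "iri", "aop:61"),
    _x("aop.stressor:208", "dcterms:isPartOf", "iri", "aop:323"),
    # --- chemical: acetaminophen -------------------------------------------
    _x("cas:103-90-2", "rdf:type", "iri", "cheminf:000000"),
    _x("cas:103-90-2", "rdf:type", "iri", "cheminf:000446"),
    _x("cas:103-90-2", "dc:identifier", "iri", "cas:103-90-2"),
    _x("cas:103-90-2", "cheminf:000446", "literal", "103-90-2"),
    _x("cas:103-90-2", "dc:title", "literal", "Acetaminophen"),
    _x("cas:103-90-2", "dcterms:alternative", "literal", "4-Acetamidophenol"),
    _x("cas:103-90-2", "dcterms:alternative", "literal", "Paracetamol"),
    _x("cas:103-90-2", "cheminf:000059", "iri", "inchikey:RZVAJINKPMORJF-UHFFFAOYSA-N"),
    _x("cas:103-90-2", "cheminf:000568", "iri", "comptox:DTXSID2020006"),
    _x("cas:103-90-2", "skos:exactMatch", "iri", "chebi:46195"),
    _x("cas:103-90-2", "skos:exactMatch", "iri", "chemspider:1906"),
    _x("cas:103-90-2", "skos:exactMatch", "iri", "wikidata:Q57055"),
    _x("cas:103-90-2", "dcterms:isPartOf", "iri", "aop.stressor:57"),
)


def missing_exemplars(main_graph, gene_graph, registry) -> list[str]:
    """Which canonical exemplar triples are absent from the given graphs
    (empty list means full reproduction)."""
    from rdflib import Literal, URIRef  # local import keeps module light

    missing = []
    for ex in CANONICAL_EXEMPLARS:
        graph = gene_graph if ex.graph == "genes" else main_graph
        s = registry.uri(ex.subject)
        p = registry.uri(ex.predicate)
        ok = False
        if ex.kind == "iri":
            ok = (s, p, registry.uri(ex.value)) in graph
        elif ex.kind == "typed":
            obj = Literal(ex.value, datatype=registry.uri(ex.datatype))
            ok = (s, p, obj) in graph
        elif ex.mode == "prefix":
            ok = any(
                isinstance(o, Literal) and str(o).startswith(ex.value)
                for o in graph.objects(s, p)
            )
        else:
            ok = (s, p, Literal(ex.value)) in graph
        if not ok:
            missing.append(f"{ex.graph}: {ex.subject} {ex.predicate} {ex.value!r}")
    return missing
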