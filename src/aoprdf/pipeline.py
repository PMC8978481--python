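"""End-to-end conversion: XML dump → enriched model → three Turtle files.

The run mirrors the published workflow: parse the dump, text-scan five KE/KER
free-text fields against the HGNC symbol dictionary, map PR biological-object
terms to gene/protein identifiers, expand chemicals and matched genes through
the identifier-mapping backend, then emit the main graph, the gene graph and
the VoID metadata graph.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from rdflib import Graph

from . import emit, genes, model as wiki_model, xrefs as xref_mod
from .emit import VoidConfig
from .genes import SymbolDictionary, TextMatch
from .model import KnowledgeModel
from .vocab import VocabRegistry, load_registry
from .xrefs import MapperBackend, XrefRecord

logger = logging.getLogger(__name__)

__all__ = ["ConvertResult", "convert", "scan_model"]


@dataclass
class ConvertResult:
    model: KnowledgeModel
    main_graph: Graph
    gene_graph: Graph
    void_graph: Graph
    matches: dict[tuple[str, int, str], set[TextMatch]] = dc_field(default_factory=dict)
    entity_genes: dict[tuple[str, int], set[str]] = dc_field(default_factory=dict)
    chemical_xrefs: dict[str, set[XrefRecord]] = dc_field(default_factory=dict)
    gene_xrefs: dict[str, set[XrefRecord]] = dc_field(default_factory=dict)
    pr_xrefs: dict[str, set[XrefRecord]] = dc_field(default_factory=dict)
    files: dict[str, Path] = dc_field(default_factory=dict)

    def summary(self) -> dict:
        m = self.model
        return {
            "aops": len(m.aops),
            "kes": len(m.kes),
            "kers": len(m.kers),
            "stressors": len(m.stressors),
            "chemicals": len(m.chemicals),
            "terms": len(m.terms),
            "text_mapped_genes": len({g for gs in self.entity_genes.values() for g in gs}),
            "chemical_xrefs": sum(len(v) for v in self.chemical_xrefs.values()),
            "gene_xrefs": sum(len(v) for v in self.gene_xrefs.values()),
            "pr_xrefs": sum(len(v) for v in self.pr_xrefs.values()),
            "triples_main": len(self.main_graph),
            "triples_genes": len(self.gene_graph),
            "triples_void": len(self.void_graph),
            "warnings": len(m.report.warnings),
            "files": {k: str(v) for k, v in self.files.items()},
        }

    def write_summary(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.summary(), indent=2, sort_keys=True) + "\n")
        return path


def scan_model(
    model: KnowledgeModel, dictionary: SymbolDictionary
) -> tuple[dict[tuple[str, int, str], set[TextMatch]], dict[tuple[str, int], set[str]]]:
    """Scan the five gene-bearing text fields of every KE and KER.

    Returns the full per-field match audit and the per-entity deduplicated
    HGNC id sets used for triple emission.
    """
    audit: dict[tuple[str, int, str], set[TextMatch]] = {}
    per_entity: dict[tuple[str, int], set[str]] = {}

    def scan(kind: str, entity_id: int, field_name: str, text: str | None) -> None:
        if not text:
            return
        found = dictionary.scan(text, field_name)
        if found:
            audit[(kind, entity_id, field_name)] = found
            per_entity.setdefault((kind, entity_id), set()).update(
                m.hgnc_id for m in found
            )

    for ke in model.kes.values():
        scan("ke", ke.id, "ke_description", ke.description)
        scan("ke", ke.id, "mie_ao_section", ke.mie_ao_section)
    for ker in model.kers.values():
        scan("ker", ker.id, "ker_description", ker.description)
        scan("ker", ker.id, "biological_plausibility", ker.biological_plausibility)
        scan("ker", ker.id, "empirical_support", ker.empirical_support)
    return audit, per_entity


def convert(
    xml_path: str | Path | KnowledgeModel,
    hgnc_table: str | Path | None = None,
    pr_table: str | Path | None = None,
    backend: MapperBackend | None = None,
    dialect: dict | str | Path | None = None,
    outdir: str | Path | None = None,
    void_config: VoidConfig | None = None,
    gene_mapping: bool = True,
    registry: VocabRegistry | None = None,
    file_names: tuple[str, str, str] = (
        "AOP-Wiki.ttl", "AOP-Wiki-genes.ttl", "AOP-Wiki-void.ttl",
    ),
) -> ConvertResult:
    """Run the full conversion.

    Gene text-mapping requires *hgnc_table*; identifier expansion requires a
    *backend* (static table or HTTP). Each enrichment degrades gracefully to
    "absent" when its input is not given. When *outdir* is set the three
    Turtle files are written there with deterministic content.
    """
    reg = registry or load_registry()
    if isinstance(xml_path, KnowledgeModel):
        model = xml_path
    else:
        model = wiki_model.parse_aopwiki_xml(xml_path, dialect)

    audit: dict = {}
    per_entity: dict = {}
    if gene_mapping and hgnc_table is not None:
        dictionary = genes.build_symbol_dictionary(hgnc_table)
        audit, per_entity = scan_model(model, dictionary)
    elif gene_mapping and hgnc_table is None:
        logger.info("no HGNC table supplied; gene text-mapping skipped")

    pr_xrefs: dict[str, set[XrefRecord]] = {}
    if pr_table is not None:
        mapping = genes.load_pr_mapping(pr_table)
        for term in model.terms.values():
            if term.kind == "object" and term.curie and term.curie.upper().startswith("PR:"):
                found = genes.map_pr_term(term.curie.replace("PR:", "pr:", 1), mapping)
                if found:
                    pr_xrefs[term.key] = found

    chemical_xrefs: dict[str, set[XrefRecord]] = {}
    gene_xrefs: dict[str, set[XrefRecord]] = {}
    if backend is not None:
        for cas in model.chemicals:
            found = xref_mod.map_chemical(cas, backend)
            if found:
                chemical_xrefs[cas] = found
        matched_genes = sorted({g for gs in per_entity.values() for g in gs})
        for hgnc_id in matched_genes:
            found = xref_mod.map_gene(hgnc_id, backend)
            if found:
                gene_xrefs[hgnc_id] = found

    main_graph = emit.build_main_graph(model, reg, chemical_xrefs, pr_xrefs)
    gene_graph = emit.build_gene_graph(per_entity, gene_xrefs, reg)
    vc = void_config or VoidConfig()
    if vc.snapshot_date is None:
        vc.snapshot_date = model.snapshot_date
    vc.main_name, vc.genes_name = file_names[0], file_names[1]
    void_graph = emit.build_void_graph(main_graph, gene_graph, reg, vc)

    result = ConvertResult(
        model=model,
        main_graph=main_graph,
        gene_graph=gene_graph,
        void_graph=void_graph,
        matches=audit,
        entity_genes=per_entity,
        chemical_xrefs=chemical_xrefs,
        gene_xrefs=gene_xrefs,
        pr_xrefs=pr_xrefs,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, graph in zip(
            file_names, (main_graph, gene_graph, void_graph)
        ):
            result.files[name] = emit.serialize_turtle(graph, outdir / name, reg)
    return result
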