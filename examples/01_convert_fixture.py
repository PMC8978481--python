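"""Convert a small wiki dump into the three Turtle files.

Builds the bundled canonical example wiki (pathways, key events,
relationships, stressors, chemicals, ontology terms plus companion
identifier tables), runs the full conversion and prints the run summary.
"""

import tempfile
from pathlib import Path

from aoprdf import convert, fixtures
from aoprdf.xrefs import static_backend

tmp = Path(tempfile.mkdtemp())
bundle = fixtures.canonical_fixture(tmp / "fixture")
result = convert(
    bundle.xml_path,
    hgnc_table=bundle.hgnc_path,          # gene text-mapping dictionary
    pr_table=bundle.pr_path,              # PRotein Ontology -> gene/protein ids
    backend=static_backend(bundle.xref_path),  # CAS/HGNC cross-references
    outdir=tmp / "out",
)

for key, value in sorted(result.summary().items()):
    print(f"{key}: {value}")

# aops/kes/kers/... are the parsed entity counts; triples_main and
# triples_genes are the sizes of the emitted main and gene graphs;
# text_mapped_genes counts distinct HGNC symbols found in free text.
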