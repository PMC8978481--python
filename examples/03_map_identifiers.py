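"""Expand CAS and HGNC identifiers to external databases.

A static cross-reference table backend stands in for a live BridgeDb-style
identifier mapping service; the library also ships an HTTP backend with the
same contract (xrefs.http_backend).
"""

import tempfile
from pathlib import Path

from aoprdf import fixtures
from aoprdf.xrefs import map_chemical, map_gene, static_backend

bundle = fixtures.canonical_fixture(Path(tempfile.mkdtemp()))
backend = static_backend(bundle.xref_path)

print("acetaminophen (CAS 103-90-2):")
for x in sorted(map_chemical("103-90-2", backend)):
    print(f"  {x.target_db}: {x.target_id}")

print("UROD (HGNC symbol):")
for x in sorted(map_gene("UROD", backend)):
    print(f"  {x.target_db}: {x.target_id}")

# The chemical expands into the nine covered chemical databases; the gene
# into NCBI Gene, UniProt and Ensembl. Each mapping becomes a typed
# skos:exactMatch link in the emitted RDF.
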