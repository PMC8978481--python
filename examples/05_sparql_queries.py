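"""Run catalog SPARQL queries against a converted graph.

The catalog bundles statistics queries, worked biological examples (e.g.
measurement methods of key events leading to an adverse outcome) and a
federated WikiPathways template (needs network; not executed here).
"""

import tempfile
from pathlib import Path

from aoprdf import convert, fixtures, query_catalog
from aoprdf.xrefs import static_backend

tmp = Path(tempfile.mkdtemp())
bundle = fixtures.canonical_fixture(tmp / "fixture")
result = convert(bundle.xml_path, hgnc_table=bundle.hgnc_path,
                 pr_table=bundle.pr_path,
                 backend=static_backend(bundle.xref_path))

catalog = {q.name: q for q in query_catalog()}
print("catalog:", ", ".join(sorted(catalog)))

rows = result.main_graph.query(catalog["ke_measurement_methods"].text)
print("\nkey events with measurement methods, per pathway:")
for row in rows:
    print(f"  {row.aop} -> {row.ke}\n    {row.title}: {str(row.method)[:60]}...")

federated = catalog["federated_wikipathways"]
print("\nfederated template (network required:", federated.network_required,
      ") declares SERVICE:", "SERVICE" in federated.text)
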