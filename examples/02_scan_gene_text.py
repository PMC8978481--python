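"""Find gene mentions in free text with the HGNC symbol dictionary.

Exact, boundary-aware matching: a symbol only counts when flanked by
separators or the string edge, so "sURODx" never matches UROD. Symbols are
case-sensitive, full gene names case-insensitive.
"""

from aoprdf.fixtures import mini_hgnc_path
from aoprdf.genes import build_symbol_dictionary, scan_text, unique_gene_ids

dictionary = build_symbol_dictionary(mini_hgnc_path())
text = (
    "Reduced UROD enzyme activity, not protein levels, drives porphyrin "
    "accumulation; the sURODx construct and urod transcript are not gene "
    "mentions, but tumor protein p53 is."
)

matches = scan_text(text, dictionary, field_name="ker_description")
for m in sorted(matches, key=lambda m: m.start):
    print(f"{m.hgnc_id:6s} {m.surface_form!r} at {m.start}:{m.end}")
print("gene ids for triple emission:", sorted(unique_gene_ids(matches)))

# Expected: one UROD hit (the embedded "sURODx" and lowercased "urod" are
# ignored) and two TP53 hits — the case-insensitive full name and its "p53"
# alias — which deduplicate to a single TP53 gene id for emission.
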