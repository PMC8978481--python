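# name: genes_per_ke
# category: example
# Text-mapped gene identifiers per key event / key event relationship
# (run against the gene graph or the union).
PREFIX edam: <http://edamontology.org/>
SELECT ?entity ?gene
WHERE { ?entity edam:data_1025 ?gene }
ORDER BY ?entity ?gene
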