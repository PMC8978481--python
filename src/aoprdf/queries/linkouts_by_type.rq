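# name: linkouts_by_type
# category: statistics
# Link-outs: skos:exactMatch targets partitioned by their database type.
PREFIX skos: <http://www.w3.org/2004/02/skos/core#>
SELECT ?type (COUNT(?o) AS ?n)
WHERE { ?s skos:exactMatch ?o . ?o a ?type }
GROUP BY ?type
ORDER BY DESC(?n) ?type
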