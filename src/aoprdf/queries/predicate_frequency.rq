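# name: predicate_frequency
# category: statistics
# Frequency of each predicate (ontology term usage).
SELECT ?p (COUNT(*) AS ?n)
WHERE { ?s ?p ?o }
GROUP BY ?p
ORDER BY DESC(?n) ?p
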