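# name: count_totals
# category: statistics
# Totals of the loaded graph: unique triples, subjects, predicates, objects.
SELECT (COUNT(*) AS ?triples)
       (COUNT(DISTINCT ?s) AS ?subjects)
       (COUNT(DISTINCT ?p) AS ?predicates)
       (COUNT(DISTINCT ?o) AS ?objects)
WHERE { ?s ?p ?o }
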