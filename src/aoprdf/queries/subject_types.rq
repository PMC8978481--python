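# name: subject_types
# category: statistics
# Number of subjects per rdf:type (types of subjects statistic).
SELECT ?type (COUNT(DISTINCT ?s) AS ?n)
WHERE { ?s a ?type }
GROUP BY ?type
ORDER BY DESC(?n) ?type
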