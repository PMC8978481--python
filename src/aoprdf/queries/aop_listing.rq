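# name: aop_listing
# category: example
# Every adverse outcome pathway with its title.
PREFIX dc: <http://purl.org/dc/elements/1.1/>
PREFIX aopo: <http://aopkb.org/aop_ontology#>
SELECT ?aop ?title
WHERE { ?aop a aopo:AdverseOutcomePathway ; dc:title ?title }
ORDER BY ?aop
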