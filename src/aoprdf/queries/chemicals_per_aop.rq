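# name: chemicals_per_aop
# category: example
# Chemicals linked to each AOP through its stressors.
PREFIX dc: <http://purl.org/dc/elements/1.1/>
PREFIX aopo: <http://aopkb.org/aop_ontology#>
PREFIX nci: <http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#>
SELECT ?aop ?stressor ?chemical ?name
WHERE {
  ?aop a aopo:AdverseOutcomePathway ; nci:C54571 ?stressor .
  ?stressor aopo:has_chemical_entity ?chemical .
  ?chemical dc:title ?name .
}
ORDER BY ?aop ?stressor ?chemical
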