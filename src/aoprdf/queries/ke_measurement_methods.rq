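# name: ke_measurement_methods
# category: example
# Measurement methods of all key events belonging to AOPs that end in a
# given adverse outcome (bind ?ao or remove the FILTER to list all).
PREFIX dc: <http://purl.org/dc/elements/1.1/>
PREFIX aopo: <http://aopkb.org/aop_ontology#>
PREFIX mmo: <http://purl.obolibrary.org/obo/MMO_>
SELECT ?aop ?ke ?title ?method
WHERE {
  ?aop a aopo:AdverseOutcomePathway ;
       aopo:has_adverse_outcome ?ao ;
       aopo:has_key_event ?ke .
  ?ke dc:title ?title ;
      mmo:0000000 ?method .
}
ORDER BY ?aop ?ke
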