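# name: federated_wikipathways
# category: federated
# network-required: yes (untested offline)
# For every chemical with a ChEBI mapping, find its stressors and AOPs, then
# join the remote WikiPathways endpoint on the ChEBI identifier to list the
# human molecular pathways the chemical takes part in.
PREFIX dc: <http://purl.org/dc/elements/1.1/>
PREFIX dcterms: <http://purl.org/dc/terms/>
PREFIX skos: <http://www.w3.org/2004/02/skos/core#>
PREFIX aopo: <http://aopkb.org/aop_ontology#>
PREFIX cheminf: <http://semanticscience.org/resource/CHEMINF_>
PREFIX nci: <http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#>
PREFIX wp: <http://vocabularies.wikipathways.org/wp#>
SELECT DISTINCT ?chemical ?name ?chebi ?stressor ?aop ?pathway ?pathwayTitle
WHERE {
  ?chemical a cheminf:000000 ;
            dc:title ?name ;
            skos:exactMatch ?chebi ;
            dcterms:isPartOf ?stressor .
  ?aop a aopo:AdverseOutcomePathway ;
       nci:C54571 ?stressor .
  ?chebi a cheminf:000407 .
  SERVICE <https://sparql.wikipathways.org/sparql> {
    ?wpChemical wp:bdbChEBI ?chebi ;
                dcterms:isPartOf ?pathway .
    ?pathway a wp:Pathway ;
             dc:title ?pathwayTitle ;
             wp:organismName "Homo sapiens" .
  }
}
ORDER BY ?chemical ?pathway
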