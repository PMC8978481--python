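# XML fixture dialect and dialect mapping

The parser reads a documented element dialect; every element/attribute name
can be remapped through a YAML dialect file (`aoprdf convert --dialect`),
so dumps with different spellings are adapted without code changes.

## Document shape

```xml
<data snapshot-date="2021-01-01">
  <aop id="38">
    <title>…</title>
    <alternative-title>…</alternative-title>
    <creators>one author per line</creators>
    <abstract>…</abstract> <description>…</description>
    <status>Open for citation &amp; comment</status>
    <created>2016-11-29T18:41:16</created> <modified>…</modified>
    <sex-applicability>…</sex-applicability> <life-stage>…</life-stage>
    <applicability>…</applicability>
    <quantitative-considerations>…</quantitative-considerations>
    <weight-of-evidence>…</weight-of-evidence>
    <potential-applications>…</potential-applications>
    <overall-assessment>…</overall-assessment>
    <ke-essentiality>…</ke-essentiality>
    <key-events><key-event ref="55"/>…</key-events>
    <molecular-initiating-events><key-event ref="244"/></molecular-initiating-events>
    <adverse-outcomes><key-event ref="344"/></adverse-outcomes>
    <key-event-relationships><key-event-relationship ref="269"/>…</key-event-relationships>
    <stressors><stressor ref="9"/>…</stressors>
  </aop>

  <key-event id="1502">
    <title>…</title> <alternative-title>…</alternative-title>
    <bio-level>Molecular</bio-level>
    <description>…</description> <mie-ao-section>…</mie-ao-section>
    <measurement-method>…</measurement-method>
    <cell-term ref="CL:0000000"/> <organ-term ref="UBERON:0000062"/>
    <biological-process ref="GO:0004857"/>
    <biological-object ref="PR:000008478"/>
    <biological-action ref="WIKI:2"/>
    <taxonomy ref="NCBITAXON:10116"/> <taxonomy ref="WCS_9606"/>
    <stressor ref="340"/>                 <!-- MIEs only -->
    <sex-applicability>…</sex-applicability> <life-stage>…</life-stage>
  </key-event>

  <key-event-relationship id="865">
    <upstream ref="844"/> <downstream ref="845"/>
    <description>…</description>
    <biological-plausibility>…</biological-plausibility>
    <empirical-support>…</empirical-support>
    <uncertainties>…</uncertainties>
    <taxonomy ref="…"/> <sex-applicability/> <life-stage/>
    <created/> <modified/>
  </key-event-relationship>

  <stressor id="208">
    <title>Gemfibrozil</title> <description>…</description>
    <chemical-ref cas="25812-30-0"/>
    <created/> <modified/>
  </stressor>

  <chemical cas="103-90-2">
    <name>Acetaminophen</name>
    <synonym>Paracetamol</synonym>       <!-- repeated element -->
    <inchikey>RZVAJINKPMORJF-UHFFFAOYSA-N</inchikey>
    <comptox>DTXSID2020006</comptox>
  </chemical>

  <!-- term declarations: curie= for ontology terms, id= for free text -->
  <cell-term curie="CL:0000000" label="cell"/>
  <taxonomy id="WCS_9606" label="Homo sapiens (wiki taxon)"/>
  <biological-action id="WIKI:2" label="decreased"/>
</data>
```

Term references (`ref=`) resolve against the term declarations; CURIE-keyed
terms become IRI nodes in the RDF, free-text keys become plain literals.

## Dialect mapping

A dialect file overrides any subset of the default mapping. Path syntax per
field: `@attr` (attribute of the entity element), `tag` (child text),
`container/child@attr` (attribute list). Multi-valued text fields
(`creators`) split on `delimiter` (default newline).

```yaml
# example: a dump that calls pathways <pathway> with <name> titles
aop:
  tag: pathway
  fields:
    title: name
delimiter: "\n"
```

## Companion tables

* **HGNC table** — TSV with headers `hgnc_id, symbol, name, alias_symbol,
  alias_name`; multi-valued columns pipe-separated.
* **PR mapping** — promapping-style TSV: `PR:nnnnnnnnn <TAB> target CURIE
  <TAB> relation`; target prefixes `UniProtKB`, `HGNC` (symbol), `NCBIGene`.
* **Static xref table** — TSV `source_db, source_id, target_db, target_id`
  with database tokens `cas, chebi, chemspider, wikidata, chembl.compound,
  pubchem.compound, drugbank, kegg.compound, lipidmaps, hmdb, hgnc,
  ncbigene, uniprot, ensembl`.
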