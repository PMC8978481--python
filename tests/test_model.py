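"""XML parsing into the typed knowledge model."""

import pytest

from aoprdf.model import ParseError, model_report, parse_aopwiki_xml

SMALL = """<?xml version="1.0"?>
<data snapshot-date="2021-01-01">
  <aop id="1">
    <title>pathway one</title>
    <key-events><key-event ref="1"/><key-event ref="2"/><key-event ref="3"/></key-events>
    <molecular-initiating-events><key-event ref="1"/></molecular-initiating-events>
    <adverse-outcomes><key-event ref="3"/></adverse-outcomes>
    <key-event-relationships>
      <key-event-relationship ref="1"/><key-event-relationship ref="2"/>
    </key-event-relationships>
    <stressors><stressor ref="1"/></stressors>
  </aop>
  <aop id="2">
    <title>pathway two</title>
    <key-events><key-event ref="4"/><key-event ref="5"/></key-events>
    <key-event-relationships><key-event-relationship ref="3"/></key-event-relationships>
    <stressors><stressor ref="2"/></stressors>
  </aop>
  <key-event id="1"><title>ke one</title></key-event>
  <key-event id="2"><title>ke two</title></key-event>
  <key-event id="3"><title>ke three</title></key-event>
  <key-event id="4"><title>ke four</title></key-event>
  <key-event id="5"><title>ke five</title></key-event>
  <key-event-relationship id="1"><upstream ref="1"/><downstream ref="2"/></key-event-relationship>
  <key-event-relationship id="2"><upstream ref="2"/><downstream ref="3"/></key-event-relationship>
  <key-event-relationship id="3"><upstream ref="4"/><downstream ref="5"/></key-event-relationship>
  <key-event-relationship id="4"><upstream ref="5"/><downstream ref="4"/></key-event-relationship>
  <stressor id="1"><title>stressor one</title><chemical-ref cas="103-90-2"/></stressor>
  <stressor id="2"><title>stressor two</title></stressor>
  <stressor id="3"><title>stressor three</title></stressor>
  <chemical cas="103-90-2"><name>acetaminophen</name></chemical>
  <chemical cas="50-00-0"><name>formaldehyde</name></chemical>
</data>
"""


@pytest.fixture()
def small_model(tmp_path):
    p = tmp_path / "small.xml"
    p.write_text(SMALL)
    return parse_aopwiki_xml(p)


def test_collection_sizes_mirror_the_document(small_model):
    m = small_model
    assert (len(m.aops), len(m.kes), len(m.kers)) == (2, 5, 4)
    assert (len(m.stressors), len(m.chemicals)) == (3, 2)
    assert m.snapshot_date == "2021-01-01"
    assert m.aops[1].ke_ids == [1, 2, 3]
    assert m.aops[1].mie_ids == [1] and m.aops[1].ao_ids == [3]
    assert m.kers[2].upstream_ke == 2 and m.kers[2].downstream_ke == 3
    assert m.stressors[1].chemical_cas == ["103-90-2"]


def test_empty_document_gives_empty_model(tmp_path):
    p = tmp_path / "empty.xml"
    p.write_text("<data/>")
    m = parse_aopwiki_xml(p)
    assert not m.aops and not m.kes and not m.kers
    assert not m.stressors and not m.chemicals and not m.terms
    assert "aops: 0" in model_report(m)


def test_parsing_is_deterministic(tmp_path):
    p = tmp_path / "small.xml"
    p.write_text(SMALL)
    a, b = parse_aopwiki_xml(p), parse_aopwiki_xml(p)
    assert a.aops == b.aops and a.kes == b.kes and a.kers == b.kers
    assert a.stressors == b.stressors and a.chemicals == b.chemicals


def test_malformed_xml_raises_parse_error(tmp_path):
    p = tmp_path / "bad.xml"
    p.write_text("<data><aop id='1'>")
    with pytest.raises(ParseError):
        parse_aopwiki_xml(p)


def test_mie_outside_ke_list_is_dropped_with_warning(tmp_path):
    p = tmp_path / "mie.xml"
    p.write_text(
        """<data>
        <aop id="1"><title>t</title>
          <key-events><key-event ref="1"/></key-events>
          <molecular-initiating-events><key-event ref="99"/></molecular-initiating-events>
        </aop>
        <key-event id="1"><title>ke</title></key-event>
        </data>"""
    )
    m = parse_aopwiki_xml(p)
    assert m.aops[1].mie_ids == []
    assert any("MIE id 99" in w for w in m.report.warnings)


def test_entity_without_mandatory_field_is_skipped_not_lost(tmp_path):
    p = tmp_path / "skip.xml"
    p.write_text(
        """<data>
        <aop id="1"><title>ok</title></aop>
        <aop id="2"></aop>
        <aop><title>no id</title></aop>
        </data>"""
    )
    m = parse_aopwiki_xml(p)
    # no silent loss: parsed + skipped = elements present
    assert m.report.parsed["aops"] == 1
    assert m.report.skipped["aops"] == 2
    assert len(m.report.warnings) >= 2


def test_self_loop_relationship_rejected_at_parse(tmp_path):
    p = tmp_path / "loop.xml"
    p.write_text(
        """<data>
        <key-event id="1"><title>k</title></key-event>
        <key-event-relationship id="1"><upstream ref="1"/><downstream ref="1"/></key-event-relationship>
        </data>"""
    )
    m = parse_aopwiki_xml(p)
    assert not m.kers
    assert any("self-loop" in w for w in m.report.warnings)


def test_dangling_relationship_endpoint_is_warned_but_kept(tmp_path):
    p = tmp_path / "dangling.xml"
    p.write_text(
        """<data>
        <key-event id="1"><title>k</title></key-event>
        <key-event-relationship id="7"><upstream ref="1"/><downstream ref="42"/></key-event-relationship>
        </data>"""
    )
    m = parse_aopwiki_xml(p)
    assert 7 in m.kers  # retained
    assert m.report.dangling.get("ke") == ["42"]
    assert "ke: 42" in model_report(m)


def test_malformed_cas_and_inchikey_are_dropped(tmp_path):
    p = tmp_path / "chem.xml"
    p.write_text(
        """<data>
        <stressor id="1"><title>s</title><chemical-ref cas="not-a-cas"/></stressor>
        <chemical cas="50-00-0"><name>x</name><inchikey>short</inchikey></chemical>
        <chemical cas="bogus"><name>y</name></chemical>
        </data>"""
    )
    m = parse_aopwiki_xml(p)
    assert m.stressors[1].chemical_cas == []
    assert m.chemicals["50-00-0"].inchikey is None
    assert "bogus" not in m.chemicals


def test_model_report_lists_counts_deterministically(small_model):
    text = model_report(small_model)
    assert text.splitlines()[0] == "aops: 2"
    assert "chemicals: 2" in text
    assert model_report(small_model) == text


def test_dialect_override_renames_elements(tmp_path):
    p = tmp_path / "alt.xml"
    p.write_text(
        """<root>
        <pathway id="5"><name>renamed pathway</name></pathway>
        </root>"""
    )
    dialect = {
        "root": "root",
        "aop": {"tag": "pathway", "fields": {"title": "name"}},
    }
    m = parse_aopwiki_xml(p, dialect)
    assert m.aops[5].title == "renamed pathway"


def test_creators_split_on_configured_delimiter(tmp_path):
    p = tmp_path / "creators.xml"
    p.write_text(
        """<data>
        <aop id="1"><title>t</title><creators>Alice Example
Bob Example</creators></aop>
        </data>"""
    )
    m = parse_aopwiki_xml(p)
    assert m.aops[1].creators == ["Alice Example", "Bob Example"]
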