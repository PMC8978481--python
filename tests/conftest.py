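"""Shared fixtures: converted canonical and random bundles, scan oracle."""

from __future__ import annotations

import pytest

from aoprdf import fixtures, pipeline
from aoprdf.genes import SEPARATORS, SymbolDictionary
from aoprdf.vocab import load_registry
from aoprdf.xrefs import static_backend

_SEPS = set(SEPARATORS)


@pytest.fixture(scope="session")
def reg():
    return load_registry()


@pytest.fixture(scope="session")
def canonical(tmp_path_factory):
    """Canonical bundle converted with all enrichments, files on disk."""
    tmp = tmp_path_factory.mktemp("canonical")
    bundle = fixtures.canonical_fixture(tmp / "in")
    result = pipeline.convert(
        bundle.xml_path,
        hgnc_table=bundle.hgnc_path,
        pr_table=bundle.pr_path,
        backend=static_backend(bundle.xref_path),
        outdir=tmp / "out",
    )
    return bundle, result


@pytest.fixture(scope="session")
def random_converted(tmp_path_factory):
    """One seeded random bundle converted end to end."""
    tmp = tmp_path_factory.mktemp("random")
    config = fixtures.FixtureConfig(seed=7)
    bundle = fixtures.generate_fixture(config, tmp / "in")
    result = pipeline.convert(
        bundle.xml_path,
        hgnc_table=bundle.hgnc_path,
        pr_table=bundle.pr_path,
        backend=static_backend(bundle.xref_path),
        outdir=tmp / "out",
    )
    return bundle, result


def brute_force_scan(text: str, dictionary: SymbolDictionary) -> set[tuple[str, int, int]]:
    """Independent oracle: enumerate every occurrence of every dictionary
    form with str.find and check the boundary characters explicitly."""
    out: set[tuple[str, int, int]] = set()
    entries = [(f, h, True) for f, h in dictionary.forms.items()] + [
        (f, h, False) for f, h in dictionary.ci_forms.items()
    ]
    for form, hgnc, case_sensitive in entries:
        hay = text if case_sensitive else text.lower()
        needle = form if case_sensitive else form.lower()
        start = 0
        while True:
            i = hay.find(needle, start)
            if i < 0:
                break
            j = i + len(needle)
            before_ok = i == 0 or text[i - 1] in _SEPS
            after_ok = j == len(text) or text[j] in _SEPS
            if before_ok and after_ok:
                out.add((hgnc, i, j))
            start = i + 1
    return out
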