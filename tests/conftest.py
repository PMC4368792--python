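"""Shared fixtures: small hand-written ontologies and generated bundles."""

from __future__ import annotations

import io
import logging

import pytest

from annoflow.corpus import build_corpus, parse_gaf
from annoflow.fixtures import FixtureSpec, build_fixture
from annoflow.ontology import parse_obo

logging.getLogger("annoflow").setLevel(logging.ERROR)

ASPECT = "synthetic_process"

CHAIN_OBO = """format-version: 1.2
ontology: synthetic-fixture

[Term]
id: T:0000001
name: root
namespace: synthetic_process

[Term]
id: T:0000002
name: middle
namespace: synthetic_process
alt_id: T:0000099
is_a: T:0000001

[Term]
id: T:0000003
name: leaf
namespace: synthetic_process
is_a: T:0000002
"""


def gaf_text(rows: list[tuple[str, str, str]], qualifier: str = "") -> str:
    """Build GAF 2.2 text from (accession, term, evidence) rows."""
    lines = ["!gaf-version: 2.2"]
    for accession, term, evidence in rows:
        lines.append(
            "\t".join(
                [
                    "DB", accession, accession, qualifier, term, "REF:1",
                    evidence, "", "S", "", "", "protein", "taxon:1",
                    "20150320", "DB", "", "",
                ]
            )
        )
    return "\n".join(lines) + "\n"


@pytest.fixture
def chain_ontology():
    """Three-term is_a chain: leaf -> middle -> root."""
    return parse_obo(io.StringIO(CHAIN_OBO))


@pytest.fixture
def chain_corpus(chain_ontology):
    """Two proteins: A on the leaf, B on the middle term."""
    rows = [("A", "T:0000003", "IDA"), ("B", "T:0000002", "IEA")]
    return build_corpus(parse_gaf(io.StringIO(gaf_text(rows))), chain_ontology)


@pytest.fixture
def planted_bundle():
    """Default planted study scenario (20 of 200, 80% vs 10%)."""
    return build_fixture(FixtureSpec(seed=11).with_planted())


def make_bundle(seed: int, planted: bool = True, **kwargs):
    spec = FixtureSpec(seed=seed, **kwargs)
    if planted:
        spec = spec.with_planted()
    return build_fixture(spec)
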