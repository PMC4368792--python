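"""Fisher exact testing, Elim decorrelation and re-rooted views."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annoflow.corpus import build_corpus, parse_gaf
from annoflow.enrichment import (
    ContingencyTable,
    EnrichmentError,
    elim,
    enrich_view,
    fisher_p,
    term_for_term,
)
from annoflow.sets import ProteinSet, build_annotation_graph, reroot

from conftest import ASPECT, gaf_text, make_bundle
from oracles import elim_oracle, hypergeom_tail_oracle


def _graph_and_universe(bundle):
    graph = build_annotation_graph(
        bundle.study, bundle.corpus, bundle.ontology, ASPECT
    )
    return graph, bundle.collection.universe


# -- fisher_p ----------------------------------------------------------------

def test_zero_successes_gives_p_one():
    assert fisher_p(ContingencyTable(k=0, n=10, K=5, N_pop=50)) == 1.0


def test_study_equal_to_universe_gives_p_one():
    for k, K in [(3, 3), (7, 7), (0, 0)]:
        table = ContingencyTable(k=k, n=20, K=K, N_pop=20)
        assert fisher_p(table) == pytest.approx(1.0)


def test_degenerate_tables_return_one():
    assert fisher_p(ContingencyTable(k=0, n=0, K=5, N_pop=50)) == 1.0
    assert fisher_p(ContingencyTable(k=0, n=5, K=0, N_pop=50)) == 1.0


def test_invalid_tables_rejected():
    with pytest.raises(EnrichmentError):
        ContingencyTable(k=6, n=5, K=10, N_pop=50)
    with pytest.raises(EnrichmentError):
        ContingencyTable(k=1, n=5, K=60, N_pop=50)


def test_depletion_alternative_is_lower_tail():
    table = ContingencyTable(k=0, n=10, K=40, N_pop=50)
    assert fisher_p(table, alternative="less") < 1e-6
    assert fisher_p(table, alternative="greater") == pytest.approx(1.0)


def test_fisher_matches_tail_sum_oracle_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(300):
        n_pop = int(rng.integers(2, 61))
        n = int(rng.integers(1, n_pop + 1))
        big_k = int(rng.integers(1, n_pop + 1))
        k = int(rng.integers(max(0, n + big_k - n_pop), min(n, big_k) + 1))
        table = ContingencyTable(k=k, n=n, K=big_k, N_pop=n_pop)
        assert fisher_p(table) == pytest.approx(
            hypergeom_tail_oracle(k, n, big_k, n_pop), abs=1e-12
        )


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.data())
def test_fisher_non_increasing_in_k(data):
    n_pop = data.draw(st.integers(5, 60))
    n = data.draw(st.integers(1, n_pop))
    big_k = data.draw(st.integers(1, n_pop))
    lo = max(0, n + big_k - n_pop)
    hi = min(n, big_k)
    previous = None
    for k in range(lo, hi + 1):
        p = fisher_p(ContingencyTable(k=k, n=n, K=big_k, N_pop=n_pop))
        if previous is not None:
            assert p <= previous + 1e-12
        previous = p


# -- term_for_term -----------------------------------------------------------

def test_term_annotating_whole_universe_gets_p_one(chain_ontology):
    rows = [(f"P{i}", "T:0000003", "IDA") for i in range(10)]
    corpus = build_corpus(parse_gaf(io.StringIO(gaf_text(rows))), chain_ontology)
    study = ProteinSet.from_accessions("s", [f"P{i}" for i in range(3)])
    graph = build_annotation_graph(study, corpus, chain_ontology, ASPECT)
    universe = [f"P{i}" for i in range(10)]
    results = term_for_term(graph, study, universe, corpus)
    assert all(r.p_value == pytest.approx(1.0) for r in results.values())


def test_tables_mirror_graph_occurrences(planted_bundle):
    graph, universe = _graph_and_universe(planted_bundle)
    results = term_for_term(graph, planted_bundle.study, universe,
                            planted_bundle.corpus)
    assert set(results) == set(graph.nodes)
    for term, result in results.items():
        assert result.table.k == graph.nodes[term].occurrence
        assert result.table.n == len(planted_bundle.study)
        assert result.table.N_pop == len(universe)


def test_exclusive_planted_term_attains_minimum_p(chain_ontology):
    # the leaf annotates exactly the 20 study proteins in an 80-protein universe
    rows = [(f"S{i:02d}", "T:0000003", "IDA") for i in range(20)]
    rows += [(f"B{i:02d}", "T:0000002", "IDA") for i in range(60)]
    corpus = build_corpus(parse_gaf(io.StringIO(gaf_text(rows))), chain_ontology)
    study = ProteinSet.from_accessions("s", [f"S{i:02d}" for i in range(20)])
    universe = [f"S{i:02d}" for i in range(20)] + [f"B{i:02d}" for i in range(60)]
    graph = build_annotation_graph(study, corpus, chain_ontology, ASPECT)
    results = term_for_term(graph, study, universe, corpus)
    best = min(results, key=lambda t: results[t].p_value)
    assert best == "T:0000003"
    assert results[best].p_value < 1e-15


def test_study_outside_universe_is_an_error(planted_bundle):
    graph, _ = _graph_and_universe(planted_bundle)
    with pytest.raises(EnrichmentError, match="outside the universe"):
        term_for_term(
            graph, planted_bundle.study,
            list(planted_bundle.study.accessions)[:5],
            planted_bundle.corpus,
        )


# -- elim --------------------------------------------------------------------

def test_elim_alpha_limit_reduces_to_term_for_term(planted_bundle):
    graph, universe = _graph_and_universe(planted_bundle)
    plain = term_for_term(graph, planted_bundle.study, universe,
                          planted_bundle.corpus)
    limit = elim(graph, planted_bundle.study, universe,
                 planted_bundle.corpus, elim_alpha=1e-300)
    for term in plain:
        assert limit[term].p_value == plain[term].p_value
        assert limit[term].table == plain[term].table
        assert not limit[term].eliminated_accessions


def test_fully_eliminated_parent_tested_at_zero(chain_ontology):
    """A parent annotated only via a significant leaf ends with k = 0, p = 1."""
    rows = [(f"S{i:02d}", "T:0000003", "IDA") for i in range(10)]
    rows += [(f"B{i:02d}", "T:0000002", "IDA") for i in range(90)]
    corpus = build_corpus(parse_gaf(io.StringIO(gaf_text(rows))), chain_ontology)
    study = ProteinSet.from_accessions("s", [f"S{i:02d}" for i in range(10)])
    universe = [f"S{i:02d}" for i in range(10)] + [f"B{i:02d}" for i in range(90)]
    graph = build_annotation_graph(study, corpus, chain_ontology, ASPECT)
    results = elim(graph, study, universe, corpus, elim_alpha=0.05)
    assert results["T:0000003"].p_value < 0.05
    assert results["T:0000002"].table.k == 0
    assert results["T:0000002"].p_value == 1.0
    assert results["T:0000002"].eliminated_accessions == frozenset(
        f"S{i:02d}" for i in range(10)
    )


def test_elim_invalid_alpha_rejected(planted_bundle):
    graph, universe = _graph_and_universe(planted_bundle)
    for alpha in (0.0, -0.1, 1.5):
        with pytest.raises(EnrichmentError):
            elim(graph, planted_bundle.study, universe,
                 planted_bundle.corpus, elim_alpha=alpha)


@pytest.mark.parametrize("seed", list(range(6)))
def test_elim_tables_match_independent_oracle(seed):
    """Per-term tested tables equal a from-scratch two-pass re-implementation."""
    bundle = make_bundle(seed, n_terms=30, n_proteins=120, study_size=20)
    graph, universe = _graph_and_universe(bundle)
    results = elim(graph, bundle.study, universe, bundle.corpus, elim_alpha=0.05)

    universe_members = {}
    study = frozenset(bundle.study.accessions)
    for term in graph.nodes:
        members = frozenset(
            acc for acc in universe
            if term in bundle.corpus.annotated_terms(acc, ASPECT)
        )
        universe_members[term] = members
    study_members = {t: m & study for t, m in universe_members.items()}
    expected = elim_oracle(
        study_members, universe_members,
        list(graph.flow_edges), len(bundle.study), len(universe), 0.05,
    )
    for term, result in results.items():
        table = result.table
        assert (table.k, table.n, table.K, table.N_pop) == expected[term]


@pytest.mark.parametrize("seed", [0, 3])
def test_elim_p_never_below_term_for_term_when_elimination_occurred(seed):
    bundle = make_bundle(seed)
    graph, universe = _graph_and_universe(bundle)
    plain = term_for_term(graph, bundle.study, universe, bundle.corpus)
    decorrelated = elim(graph, bundle.study, universe, bundle.corpus)
    for term in plain:
        if decorrelated[term].eliminated_accessions:
            # small slack: sf() accumulates ~1e-12 of float noise near p = 1
            assert decorrelated[term].p_value >= plain[term].p_value - 1e-9
        else:
            assert decorrelated[term].p_value == plain[term].p_value


# -- enrich_view -------------------------------------------------------------

def test_view_at_aspect_root_is_unrestricted(planted_bundle):
    bundle = planted_bundle
    graph, universe = _graph_and_universe(bundle)
    root = bundle.ontology.roots[ASPECT]
    via_view = enrich_view(graph, bundle.collection, bundle.study,
                           bundle.corpus, root, method="tft")
    direct = term_for_term(graph, bundle.study, universe, bundle.corpus)
    for term in direct:
        assert via_view[term].p_value == direct[term].p_value


@pytest.mark.parametrize("seed", [1, 5])
def test_rerooted_view_equals_manual_restriction(seed):
    """Restricted p-values equal direct computation on restricted lists."""
    bundle = make_bundle(seed)
    graph, universe = _graph_and_universe(bundle)
    root = bundle.ontology.roots[ASPECT]
    non_leaves = [t for t in sorted(graph.nodes)
                  if not graph.is_leaf(t) and t != root]
    new_root = non_leaves[0]
    view = reroot(graph, new_root)
    results = enrich_view(view, bundle.collection, bundle.study,
                          bundle.corpus, root, method="tft")

    restricted_universe = [
        acc for acc in sorted(universe)
        if new_root in bundle.corpus.annotated_terms(acc, ASPECT)
    ]
    restricted_study = [
        acc for acc in bundle.study.accessions if acc in restricted_universe
    ]
    manual = term_for_term(view, restricted_study, restricted_universe,
                           bundle.corpus)
    assert set(results) == set(view.nodes)
    for term in results:
        assert results[term].p_value == manual[term].p_value
        assert results[term].table == manual[term].table


def test_view_root_occurrence_defines_margins(planted_bundle):
    bundle = planted_bundle
    graph, _ = _graph_and_universe(bundle)
    root = bundle.ontology.roots[ASPECT]
    non_leaves = [t for t in sorted(graph.nodes)
                  if not graph.is_leaf(t) and t != root]
    view = reroot(graph, non_leaves[0])
    results = enrich_view(view, bundle.collection, bundle.study,
                          bundle.corpus, root, method="tft")
    any_result = next(iter(results.values()))
    assert any_result.table.n == view.annotated_in_set
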