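"""Term-for-term Fisher enrichment and topology-based Elim decorrelation.

Each term of a Set's annotation graph is tested against the Collection
universe with a one-sided Fisher exact test (hypergeometric upper tail):
under the null, the study Set is an exchangeable random draw from the
Collection, so the number of study proteins carrying the term follows a
hypergeometric law.

Because annotations propagate, a term's count is never smaller than any
descendant's, which correlates the tests along every root-ward path.  The
Elim strategy mitigates this: terms are processed most-specific-first,
level by level, and once a term is significant at ``elim_alpha`` its
annotated proteins are eliminated from the counts of all its ancestors
before those are tested.

Re-rooted graph views are tested over the *current view* only: the
universe shrinks to the Collection proteins annotated under the view's
root, the study to its Set members under that root, and the term list to
the view's nodes.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import hypergeom

from .corpus import AnnotationCorpus
from .sets import AnnotationGraph, Collection, ProteinSet, propagated_membership

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    """Raised for invalid study/universe configurations."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts behind one Fisher test.

    k: study proteins annotated with the term; n: study size;
    K: universe proteins annotated with the term; N_pop: universe size.
    """

    k: int
    n: int
    K: int
    N_pop: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and
                self.n <= self.N_pop and self.K <= self.N_pop):
            raise EnrichmentError(f"inconsistent contingency table: {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    p_value: float
    table: ContingencyTable
    eliminated_accessions: frozenset[str] = frozenset()


def fisher_p(table: ContingencyTable, alternative: str = "greater") -> float:
    """One-sided Fisher exact p-value for the table.

    ``greater`` tests enrichment (upper hypergeometric tail
    P(X >= k)); ``less`` tests depletion.  Degenerate tables (empty
    study or term) return 1 by convention.
    """
    if table.n == 0 or table.K == 0:
        logger.debug("degenerate table %s: p = 1 by convention", table)
        return 1.0
    if alternative == "greater":
        p = float(hypergeom.sf(table.k - 1, table.N_pop, table.K, table.n))
    elif alternative == "less":
        p = float(hypergeom.cdf(table.k, table.N_pop, table.K, table.n))
    else:
        raise EnrichmentError(f"unknown alternative {alternative!r}")
    return min(1.0, max(0.0, p))


def _resolve_universe(background: Collection | Iterable[str]) -> frozenset[str]:
    if isinstance(background, Collection):
        return background.universe
    return frozenset(background)


def _study_accessions(study: ProteinSet | Iterable[str]) -> frozenset[str]:
    if isinstance(study, ProteinSet):
        return frozenset(study.accessions)
    return frozenset(study)


def _counts(
    graph: AnnotationGraph,
    study: frozenset[str],
    universe: frozenset[str],
    corpus: AnnotationCorpus,
    annotated_only: bool,
) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]], int, int]:
    """Per-term member sets for study and universe, plus n and N_pop."""
    if not study <= universe:
        raise EnrichmentError(
            f"{len(study - universe)} study accessions are outside the universe"
        )
    universe_members = {
        term: frozenset(accs)
        for term, accs in propagated_membership(universe, corpus, graph.aspect).items()
        if term in graph.nodes
    }
    study_members = {
        term: accs & study for term, accs in universe_members.items()
    }
    if annotated_only:
        root = graph.root_term
        annotated_universe = universe_members.get(root, frozenset())
        n = len(study & annotated_universe)
        n_pop = len(annotated_universe)
    else:
        n = len(study)
        n_pop = len(universe)
    return study_members, universe_members, n, n_pop


def term_for_term(
    graph: AnnotationGraph,
    study: ProteinSet | Iterable[str],
    background: Collection | Iterable[str],
    corpus: AnnotationCorpus,
    alternative: str = "greater",
    annotated_only: bool = False,
) -> dict[str, EnrichmentResult]:
    """Independent Fisher test of every graph node.

    ``annotated_only=False`` (default) keeps universe proteins without
    any annotation under the graph root in ``N_pop`` — they are genuine
    trial units; the flag drops them from both margins.
    """
    study_set = _study_accessions(study)
    universe = _resolve_universe(background)
    study_members, universe_members, n, n_pop = _counts(
        graph, study_set, universe, corpus, annotated_only
    )
    results: dict[str, EnrichmentResult] = {}
    for term in graph.nodes:
        table = ContingencyTable(
            k=len(study_members.get(term, ())),
            n=n,
            K=len(universe_members.get(term, ())),
            N_pop=n_pop,
        )
        results[term] = EnrichmentResult(
            term_id=term,
            p_value=fisher_p(table, alternative),
            table=table,
        )
    return results


def _depths(graph: AnnotationGraph) -> dict[str, int]:
    """Longest-path depth of every node from the graph root."""
    children: dict[str, list[str]] = {t: [] for t in graph.nodes}
    indeg = {t: 0 for t in graph.nodes}
    for (parent, child) in graph.flow_edges:
        children[parent].append(child)
        indeg[child] += 1
    depth = {t: 0 for t in graph.nodes}
    queue = deque(t for t, d in indeg.items() if d == 0)
    while queue:
        node = queue.popleft()
        for child in children[node]:
            depth[child] = max(depth[child], depth[node] + 1)
            indeg[child] -= 1
            if indeg[child] == 0:
                queue.append(child)
    return depth


def _graph_ancestors(graph: AnnotationGraph, term: str) -> set[str]:
    parents: dict[str, set[str]] = {}
    for (p, c) in graph.flow_edges:
        parents.setdefault(c, set()).add(p)
    seen: set[str] = set()
    queue = deque(parents.get(term, ()))
    while queue:
        node = queue.popleft()
        if node in seen:
            continue
        seen.add(node)
        queue.extend(parents.get(node, ()))
    return seen


def elim(
    graph: AnnotationGraph,
    study: ProteinSet | Iterable[str],
    background: Collection | Iterable[str],
    corpus: AnnotationCorpus,
    elim_alpha: float = 0.05,
    alternative: str = "greater",
    annotated_only: bool = False,
) -> dict[str, EnrichmentResult]:
    """Elim-decorrelated Fisher tests over the graph.

    Nodes are processed level by level in reverse-topological order
    (depth = longest path from the root; deepest first; ties broken
    lexicographically).  A term found significant at ``elim_alpha``
    marks its universe-annotated proteins for elimination from both the
    study and universe counts of every ancestor.  ``n`` and ``N_pop``
    stay fixed; only the term counts shrink.
    """
    if not (0.0 < elim_alpha <= 1.0):
        raise EnrichmentError(f"elim_alpha must be in (0, 1], got {elim_alpha}")
    study_set = _study_accessions(study)
    universe = _resolve_universe(background)
    study_members, universe_members, n, n_pop = _counts(
        graph, study_set, universe, corpus, annotated_only
    )
    depth = _depths(graph)
    levels: dict[int, list[str]] = {}
    for term, d in depth.items():
        levels.setdefault(d, []).append(term)

    elim_sets: dict[str, set[str]] = {}
    results: dict[str, EnrichmentResult] = {}
    for d in sorted(levels, reverse=True):
        significant: list[str] = []
        for term in sorted(levels[d]):
            excluded = frozenset(elim_sets.get(term, ()))
            k_members = study_members.get(term, frozenset()) - excluded
            big_k_members = universe_members.get(term, frozenset()) - excluded
            table = ContingencyTable(
                k=len(k_members), n=n, K=len(big_k_members), N_pop=n_pop
            )
            p = fisher_p(table, alternative)
            results[term] = EnrichmentResult(
                term_id=term,
                p_value=p,
                table=table,
                eliminated_accessions=excluded,
            )
            if p <= elim_alpha:
                significant.append(term)
        # eliminations from one level apply only to strictly shallower levels
        for term in significant:
            members = universe_members.get(term, frozenset())
            for ancestor in _graph_ancestors(graph, term):
                elim_sets.setdefault(ancestor, set()).update(members)
    return results


def enrich_view(
    graph: AnnotationGraph,
    collection: Collection | Iterable[str],
    study: ProteinSet | Iterable[str],
    corpus: AnnotationCorpus,
    ontology_root: str,
    method: str = "elim",
    elim_alpha: float = 0.05,
    alternative: str = "greater",
    annotated_only: bool = False,
) -> dict[str, EnrichmentResult]:
    """Enrichment over the current graph view, honouring re-roots.

    When the graph is rooted below the aspect root (``ontology_root``),
    masked terms are invisible to the test: the universe is restricted to
    collection proteins annotated under the view root and the study to
    its members under that root.  Rooted at the aspect root, this is
    plain whole-aspect testing.
    """
    study_set = _study_accessions(study)
    universe = _resolve_universe(collection)
    if graph.root_term != ontology_root:
        root_closure_members = {
            acc for acc in universe
            if graph.root_term in corpus.annotated_terms(acc, graph.aspect)
        }
        if not root_closure_members:
            raise EnrichmentError(
                f"no collection protein is annotated under {graph.root_term!r}"
            )
        universe = frozenset(root_closure_members)
        study_set = study_set & universe
        annotated_only = False  # the view root already defines the margins
    if method == "elim":
        return elim(
            graph, study_set, universe, corpus, elim_alpha, alternative,
            annotated_only,
        )
    if method in ("term_for_term", "tft"):
        return term_for_term(
            graph, study_set, universe, corpus, alternative, annotated_only
        )
    raise EnrichmentError(f"unknown method {method!r}")


def bh_adjust(results: Mapping[str, EnrichmentResult]) -> dict[str, float]:
    """Benjamini-Hochberg adjusted p-values (non-canonical companion column).

    Elim p-values are conditioned on descendants and are not independent,
    so a standard multiple-testing correction is not strictly applicable;
    this helper exists for exploratory sorting only.
    """
    items = sorted(results.items(), key=lambda kv: kv[1].p_value)
    m = len(items)
    adjusted: dict[str, float] = {}
    running = 1.0
    for rank in range(m, 0, -1):
        term, res = items[rank - 1]
        running = min(running, res.p_value * m / rank)
        adjusted[term] = running
    return adjusted
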