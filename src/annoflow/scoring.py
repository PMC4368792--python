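"""Information-content term scores.

For a term *t* with corpus annotation frequency ``f(t)`` (the fraction of
corpus proteins annotated to *t* or any propagating descendant):

    IC(t)      = -log2 f(t)                     (bits; 0 at the root)
    ICu(t)     = IC(t) / log2 N                 (scaled into [0, 1])
    ICscore(t) = ICu(t) * s(t)                  (the term score)

where ``N`` is the size of the reference corpus in the aspect and
``s(t)`` the term's annotation frequency within the current Set.  The
score weights how common a term is in the Set by how specific it is in
the corpus ("specific representativity"), and is unchanged by re-rooting
because neither factor depends on the graph view.

``N`` defaults to the number of distinct annotated corpus proteins in
the aspect, so the rarest possible term (a single protein) scores
ICu = 1 exactly; the alternative convention counting association records
is available via ``n_mode="annotations"``.  ``s(t)`` defaults to
occurrence / annotated-in-set; ``set_size`` puts the whole Set in the
denominator instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .corpus import AnnotationCorpus
from .sets import AnnotationGraph


class ScoringError(ValueError):
    """Raised when a score is undefined for the given corpus or graph."""


@dataclass(frozen=True)
class TermScore:
    term_id: str
    ic: float
    ic_scaled: float
    ic_score: float
    set_frequency: float


def ic(term_id: str, corpus: AnnotationCorpus, aspect: str) -> float:
    """Information content of a term, in bits."""
    size = corpus.corpus_size.get(aspect, 0)
    if size < 1:
        raise ScoringError(f"aspect {aspect!r} has no annotated corpus proteins")
    term = corpus.ontology.resolve(term_id)
    count = corpus.propagated_count.get(term, 0)
    if count < 1:
        raise ScoringError(f"term {term} has no corpus annotations; IC undefined")
    return -math.log2(count / size)


def _scale_denominator(corpus: AnnotationCorpus, aspect: str, n_mode: str) -> int:
    if n_mode == "proteins":
        n = corpus.corpus_size.get(aspect, 0)
    elif n_mode == "annotations":
        n = corpus.annotation_count.get(aspect, 0)
    else:
        raise ScoringError(f"unknown n_mode {n_mode!r}")
    if n < 2:
        raise ScoringError(
            f"aspect {aspect!r} has N={n}; scaling needs N >= 2"
        )
    return n


def ic_scaled(
    term_id: str, corpus: AnnotationCorpus, aspect: str, n_mode: str = "proteins"
) -> float:
    """IC divided by log2(N), clipped into [0, 1]."""
    n = _scale_denominator(corpus, aspect, n_mode)
    value = ic(term_id, corpus, aspect) / math.log2(n)
    return min(1.0, max(0.0, value))


def ic_score(
    term_id: str,
    corpus: AnnotationCorpus,
    graph: AnnotationGraph,
    n_mode: str = "proteins",
    s_denominator: str = "annotated",
) -> TermScore:
    """The scaled-IC term score for a term of a Set's annotation graph."""
    if term_id not in graph.nodes:
        raise ScoringError(f"term {term_id!r} is not in the graph")
    if s_denominator == "annotated":
        # aspect-level annotated count: invariant under re-rooting, so the
        # score of a retained term never changes with the graph view
        denom = graph.set_annotated or graph.annotated_in_set
    elif s_denominator == "set_size":
        denom = graph.set_size
    else:
        raise ScoringError(f"unknown s_denominator {s_denominator!r}")
    if denom == 0:
        raise ScoringError("set has no annotated proteins; s(t) undefined")
    scaled = ic_scaled(term_id, corpus, graph.aspect, n_mode)
    freq = graph.nodes[term_id].occurrence / denom
    return TermScore(
        term_id=term_id,
        ic=ic(term_id, corpus, graph.aspect),
        ic_scaled=scaled,
        ic_score=scaled * freq,
        set_frequency=freq,
    )


def score_graph(
    graph: AnnotationGraph,
    corpus: AnnotationCorpus,
    n_mode: str = "proteins",
    s_denominator: str = "annotated",
) -> dict[str, TermScore]:
    """Scores for every node of the graph, keyed by term id."""
    return {
        term: ic_score(term, corpus, graph, n_mode, s_denominator)
        for term in graph.nodes
    }
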