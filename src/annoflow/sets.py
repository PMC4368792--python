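"""Protein Sets, Collections and per-Set annotation flow graphs.

A Set is a named list of protein accessions under study; a Collection
groups Sets and defines the enrichment background universe.  For a Set
and an ontology aspect, the annotation graph is the sub-DAG induced by
every term that annotates at least one Set protein directly or by
inheritance.  Edges are drawn parent->child ("annotation flow"): the edge
weight counts the proteins that descend from the parent term into the
child term, which is what edge thickness encodes in the rendered graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .corpus import AnnotationCorpus
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)


class SetModelError(ValueError):
    """Raised for invalid Set/Collection/graph operations."""


@dataclass(frozen=True)
class ProteinSet:
    """An ordered, duplicate-free list of protein accessions."""

    name: str
    accessions: tuple[str, ...]
    parent_collection: str = ""

    @classmethod
    def from_accessions(
        cls, name: str, accessions: Iterable[str], parent_collection: str = ""
    ) -> "ProteinSet":
        seen: dict[str, None] = {}
        duplicates = 0
        for acc in accessions:
            if acc in seen:
                duplicates += 1
            else:
                seen[acc] = None
        if duplicates:
            logger.warning(
                "set %s: %d duplicate accessions removed", name, duplicates
            )
        return cls(name=name, accessions=tuple(seen), parent_collection=parent_collection)

    def __len__(self) -> int:
        return len(self.accessions)


@dataclass
class Collection:
    """A named group of Sets; its universe is the union of their accessions."""

    name: str
    sets: dict[str, ProteinSet] = field(default_factory=dict)

    def add(self, pset: ProteinSet) -> None:
        if pset.name in self.sets:
            raise SetModelError(
                f"collection {self.name!r} already has a set named {pset.name!r}"
            )
        self.sets[pset.name] = pset

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for pset in self.sets.values():
            out.update(pset.accessions)
        return frozenset(out)


def read_set_file(source: IO[str], name: str, collection: str = "") -> ProteinSet:
    """One accession per line; blank lines and '#' comments ignored."""
    accessions = []
    for line in source:
        line = line.strip()
        if line and not line.startswith("#"):
            accessions.append(line)
    return ProteinSet.from_accessions(name, accessions, collection)


def read_collection_tsv(source: IO[str], name: str) -> Collection:
    """Two-column TSV (set_name <tab> accession) into a Collection."""
    members: dict[str, list[str]] = {}
    for line in source:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        set_name, accession = line.split("\t")[:2]
        members.setdefault(set_name, []).append(accession)
    collection = Collection(name=name)
    for set_name, accessions in members.items():
        collection.add(ProteinSet.from_accessions(set_name, accessions, name))
    return collection


@dataclass(frozen=True)
class GraphNode:
    """Per-term statistics inside an annotation graph."""

    term_id: str
    occurrence: int
    direct: bool
    members: frozenset[str]


@dataclass
class AnnotationGraph:
    """A Set's induced annotation sub-DAG for one aspect.

    ``nodes`` maps term ids to :class:`GraphNode`; ``flow_edges`` maps
    (parent, child) pairs to the number of Set proteins shared by both
    endpoints.  ``annotated_in_set`` counts Set proteins with at least
    one annotation under ``root_term``; ``set_size`` is the whole Set,
    annotated or not.  ``set_annotated`` is the aspect-level annotated
    count of the Set and survives re-rooting unchanged — it is the
    within-Set frequency denominator of the IC term score, which must
    not depend on the current graph view.
    """

    set_name: str
    aspect: str
    root_term: str
    nodes: dict[str, GraphNode]
    flow_edges: dict[tuple[str, str], int]
    annotated_in_set: int
    set_size: int
    set_annotated: int = 0

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.nodes

    def children(self, term_id: str) -> list[str]:
        return sorted(c for (p, c) in self.flow_edges if p == term_id)

    def is_leaf(self, term_id: str) -> bool:
        return not any(p == term_id for (p, _c) in self.flow_edges)

    def occurrence(self, term_id: str) -> int:
        return self.nodes[term_id].occurrence


def propagated_membership(
    accessions: Iterable[str],
    corpus: AnnotationCorpus,
    aspect: str,
) -> dict[str, set[str]]:
    """term -> set of accessions annotated to it (directly or inherited)."""
    members: dict[str, set[str]] = {}
    for accession in accessions:
        for term in corpus.annotated_terms(accession, aspect):
            members.setdefault(term, set()).add(accession)
    return members


def build_annotation_graph(
    pset: ProteinSet,
    corpus: AnnotationCorpus,
    ontology: OntologyGraph,
    aspect: str,
) -> AnnotationGraph:
    """Build the annotation flow graph of ``pset`` in ``aspect``.

    Proteins without any annotation in the aspect count towards
    ``set_size`` but appear on no node.  Unknown aspects and empty Sets
    are errors; accessions absent from the corpus are logged.
    """
    if not pset.accessions:
        raise SetModelError(f"set {pset.name!r} has no accessions")
    if aspect not in ontology.roots:
        raise SetModelError(f"unknown aspect {aspect!r}")

    known = corpus.accessions(aspect)
    missing = [a for a in pset.accessions if a not in known]
    if missing:
        logger.info(
            "set %s: %d of %d accessions have no %s annotation",
            pset.name, len(missing), len(pset), aspect,
        )

    members = propagated_membership(pset.accessions, corpus, aspect)
    direct_terms: set[str] = set()
    for accession in pset.accessions:
        direct_terms |= {
            ontology.resolve(t)
            for t in corpus.direct_map.get(aspect, {}).get(accession, ())
        }

    nodes = {
        term: GraphNode(
            term_id=term,
            occurrence=len(accs),
            direct=term in direct_terms,
            members=frozenset(accs),
        )
        for term, accs in members.items()
    }

    flow_edges: dict[tuple[str, str], int] = {}
    for child in nodes:
        for parent in ontology.parents(child, corpus.relations):
            if parent in nodes:
                shared = nodes[parent].members & nodes[child].members
                flow_edges[(parent, child)] = len(shared)

    root = ontology.roots[aspect]
    annotated = len(members.get(root, ()))
    return AnnotationGraph(
        set_name=pset.name,
        aspect=aspect,
        root_term=root,
        nodes=nodes,
        flow_edges=flow_edges,
        annotated_in_set=annotated,
        set_size=len(pset),
        set_annotated=annotated,
    )


def reroot(graph: AnnotationGraph, new_root: str) -> AnnotationGraph:
    """Restrict the graph to ``new_root`` and its retained descendants.

    The Set stays whole (``set_size`` unchanged) but only proteins
    annotated under the new root remain on nodes, and
    ``annotated_in_set`` becomes the new root's occurrence.  Member sets
    of retained nodes are unchanged — they were already subsets of the
    new root's members by the true path rule.
    """
    if new_root not in graph.nodes:
        raise SetModelError(f"term {new_root!r} is not in the graph")
    if graph.is_leaf(new_root):
        raise SetModelError(
            f"cannot re-root at leaf term {new_root!r}: only non-leaf nodes allowed"
        )
    keep: set[str] = {new_root}
    stack = [new_root]
    while stack:
        term = stack.pop()
        for (parent, child) in graph.flow_edges:
            if parent == term and child not in keep:
                keep.add(child)
                stack.append(child)
    nodes = {t: graph.nodes[t] for t in keep}
    flow_edges = {
        (p, c): w for (p, c), w in graph.flow_edges.items() if p in keep and c in keep
    }
    return AnnotationGraph(
        set_name=graph.set_name,
        aspect=graph.aspect,
        root_term=new_root,
        nodes=nodes,
        flow_edges=flow_edges,
        annotated_in_set=graph.nodes[new_root].occurrence,
        set_size=graph.set_size,
        set_annotated=graph.set_annotated,
    )


def list_node_proteins(graph: AnnotationGraph, term_id: str) -> list[str]:
    """The node's member accessions in lexicographic order."""
    if term_id not in graph.nodes:
        raise SetModelError(f"term {term_id!r} is not in the graph")
    return sorted(graph.nodes[term_id].members)


def set_summary(graph: AnnotationGraph) -> Mapping[str, object]:
    """Header statistics for a Set/aspect pair (coverage summary)."""
    return {
        "set": graph.set_name,
        "aspect": graph.aspect,
        "root_term": graph.root_term,
        "set_size": graph.set_size,
        "annotated_in_set": graph.annotated_in_set,
        "n_terms": len(graph.nodes),
    }
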