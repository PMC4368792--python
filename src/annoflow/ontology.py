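"""Ontology DAG parsing and closure queries.

Terms live in per-aspect directed acyclic graphs whose edges point from
child to parent and carry a relation type (``is_a``, ``part_of`` or
``regulates``).  Annotation propagation follows the true path rule: an
annotation to a term implies annotation to every ancestor reachable over
the *propagating* relations, up to the aspect root.

By default only ``is_a`` and ``part_of`` propagate; ``regulates`` edges are
kept in the graph but do not carry annotations unless explicitly requested.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relations recognised on ontology edges.
RELATIONS = frozenset({"is_a", "part_of", "regulates"})

#: Relations over which annotations propagate towards the root.
PROPAGATING = frozenset({"is_a", "part_of"})


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or unknown terms."""


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology concept."""

    term_id: str
    name: str
    aspect: str
    is_obsolete: bool = False


@dataclass
class OntologyGraph:
    """Per-aspect DAGs of ontology terms with typed child->parent edges.

    ``graph`` is a :class:`networkx.MultiDiGraph` whose edge keys are the
    relation names; ``roots`` maps each aspect to its unique root term and
    ``alt_ids`` maps secondary accessions to primary ones.
    """

    graph: nx.MultiDiGraph
    roots: dict[str, str]
    alt_ids: dict[str, str] = field(default_factory=dict)
    terms: dict[str, OntologyTerm] = field(default_factory=dict)

    # -- identity ---------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Map an accession (possibly an alt_id) to its primary term id."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        raise OntologyError(f"unknown term: {term_id!r}")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_ids

    def aspect_of(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].aspect

    def name_of(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].name

    @property
    def aspects(self) -> tuple[str, ...]:
        return tuple(sorted(self.roots))

    # -- closures ---------------------------------------------------------

    def _closure(
        self,
        term_id: str,
        relations: Iterable[str],
        reverse: bool,
        include_self: bool,
    ) -> set[str]:
        start = self.resolve(term_id)
        relations = frozenset(relations)
        unknown = relations - RELATIONS
        if unknown:
            raise OntologyError(f"unknown relations: {sorted(unknown)}")
        neighbours = (
            self.graph.pred if reverse else self.graph.succ
        )
        seen: set[str] = {start}
        queue = deque([start])
        while queue:
            node = queue.popleft()
            for other, keyed in neighbours[node].items():
                if other in seen:
                    continue
                if relations.intersection(keyed):
                    seen.add(other)
                    queue.append(other)
        if not include_self:
            seen.discard(start)
        return seen

    def ancestors(
        self,
        term_id: str,
        relations: Iterable[str] = PROPAGATING,
        include_self: bool = False,
    ) -> set[str]:
        """Terms reachable from ``term_id`` towards the root."""
        return self._closure(term_id, relations, reverse=False, include_self=include_self)

    def descendants(
        self,
        term_id: str,
        relations: Iterable[str] = PROPAGATING,
        include_self: bool = False,
    ) -> set[str]:
        """Terms from which ``term_id`` is reachable (more specific terms)."""
        return self._closure(term_id, relations, reverse=True, include_self=include_self)

    def parents(self, term_id: str, relations: Iterable[str] = PROPAGATING) -> set[str]:
        term = self.resolve(term_id)
        relations = frozenset(relations)
        return {
            p
            for p, keyed in self.graph.succ[term].items()
            if relations.intersection(keyed)
        }

    def children(self, term_id: str, relations: Iterable[str] = PROPAGATING) -> set[str]:
        term = self.resolve(term_id)
        relations = frozenset(relations)
        return {
            c
            for c, keyed in self.graph.pred[term].items()
            if relations.intersection(keyed)
        }


def parse_obo(source: IO[str] | str, remap_obsolete: bool = False) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Parameters
    ----------
    source
        Path or readable handle of OBO text.
    remap_obsolete
        When true, obsolete terms carrying a ``replaced_by`` line are kept
        as aliases of their replacement; otherwise obsolete terms are
        dropped with a warning.

    Raises
    ------
    OntologyError
        On a cyclic ``is_a`` structure (one cycle is named) or when an
        aspect contains more than one root.
    """
    raw = obonet.read_obo(source, ignore_obsolete=False)

    graph = nx.MultiDiGraph()
    terms: dict[str, OntologyTerm] = {}
    alt_ids: dict[str, str] = {}

    for node, data in raw.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        namespace = data.get("namespace")
        if namespace is None and not obsolete:
            logger.warning("term %s has no namespace; rejected", node)
            continue
        if obsolete:
            replacements = data.get("replaced_by", [])
            if remap_obsolete and replacements:
                alt_ids[node] = replacements[0]
            else:
                logger.warning("obsolete term %s dropped", node)
            continue
        terms[node] = OntologyTerm(
            term_id=node,
            name=data.get("name", node),
            aspect=namespace,
            is_obsolete=False,
        )
        graph.add_node(node)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node

    for child, parent, relation in raw.edges(keys=True):
        if relation not in RELATIONS:
            logger.warning(
                "edge %s -[%s]-> %s uses an unsupported relation; dropped",
                child, relation, parent,
            )
            continue
        if child in terms and parent in terms:
            graph.add_edge(child, parent, key=relation)

    # remapped obsolete ids must point at live terms
    alt_ids = {alias: tgt for alias, tgt in alt_ids.items() if tgt in terms}

    _check_acyclic(graph)
    roots = _find_roots(graph, terms)

    ontology = OntologyGraph(graph=graph, roots=roots, alt_ids=alt_ids, terms=terms)
    _check_rooted(ontology)
    return ontology


def _check_acyclic(graph: nx.MultiDiGraph) -> None:
    is_a_view = nx.DiGraph(
        (u, v) for u, v, k in graph.edges(keys=True) if k == "is_a"
    )
    try:
        cycle = nx.find_cycle(is_a_view)
    except nx.NetworkXNoCycle:
        return
    path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
    raise OntologyError(f"cyclic is_a structure: {path}")


def _find_roots(graph: nx.MultiDiGraph, terms: dict[str, OntologyTerm]) -> dict[str, str]:
    roots: dict[str, str] = {}
    for node in terms:
        if graph.out_degree(node) == 0:
            aspect = terms[node].aspect
            if aspect in roots:
                raise OntologyError(
                    f"aspect {aspect!r} has multiple roots: "
                    f"{roots[aspect]} and {node}"
                )
            roots[aspect] = node
    for term in terms.values():
        if term.aspect not in roots:
            raise OntologyError(f"aspect {term.aspect!r} has no root")
    return roots


def _check_rooted(ontology: OntologyGraph) -> None:
    """True path rule: every term must reach its aspect root over propagating edges."""
    for term_id, term in ontology.terms.items():
        root = ontology.roots[term.aspect]
        if term_id == root:
            continue
        if root not in ontology.ancestors(term_id):
            logger.warning(
                "term %s cannot reach the %s root over propagating edges",
                term_id, term.aspect,
            )
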