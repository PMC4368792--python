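"""Independent brute-force oracles the test suite checks the package against.

Everything here is deliberately naive: closures by breadth-first search
over raw edge lists, propagated counts by exhaustive per-accession scans,
hypergeometric tails by summing log-factorial point masses, and Elim by a
re-implementation that materialises each term's elimination set from
scratch.  None of it shares code paths with the package.
"""

from __future__ import annotations

import math
import re
from collections import deque


# -- graph reachability ------------------------------------------------------

def reachable(edges: list[tuple[str, str]], start: str) -> set[str]:
    """All nodes reachable from ``start`` over directed ``edges`` (excl. start)."""
    adjacency: dict[str, list[str]] = {}
    for a, b in edges:
        adjacency.setdefault(a, []).append(b)
    seen: set[str] = set()
    queue = deque(adjacency.get(start, []))
    while queue:
        node = queue.popleft()
        if node in seen:
            continue
        seen.add(node)
        queue.extend(adjacency.get(node, []))
    seen.discard(start)
    return seen


def ancestors_oracle(edge_list: list[tuple[str, str, str]], term: str,
                     relations: set[str]) -> set[str]:
    edges = [(c, p) for c, p, r in edge_list if r in relations]
    return reachable(edges, term)


def descendants_oracle(edge_list: list[tuple[str, str, str]], term: str,
                       relations: set[str]) -> set[str]:
    edges = [(p, c) for c, p, r in edge_list if r in relations]
    return reachable(edges, term)


# -- propagated corpus counts ------------------------------------------------

def propagated_count_oracle(
    direct: dict[str, set[str]],
    edge_list: list[tuple[str, str, str]],
    relations: set[str],
    term: str,
) -> int:
    """Accessions annotated to ``term`` or any of its descendants.

    Scans every accession and tests whether its direct terms intersect the
    term's descendant closure (including the term itself).
    """
    closure = descendants_oracle(edge_list, term, relations) | {term}
    return sum(1 for terms in direct.values() if terms & closure)


def node_occurrence_oracle(
    accessions: list[str],
    direct: dict[str, set[str]],
    edge_list: list[tuple[str, str, str]],
    relations: set[str],
    term: str,
) -> set[str]:
    """Set proteins whose up-propagated term set contains ``term``."""
    out = set()
    for accession in accessions:
        propagated: set[str] = set()
        for t in direct.get(accession, ()):
            propagated |= ancestors_oracle(edge_list, t, relations) | {t}
        if term in propagated:
            out.add(accession)
    return out


# -- hypergeometric tail -----------------------------------------------------

def _log_choose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return float("-inf")
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_tail_oracle(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), via point-mass summation."""
    total = 0.0
    log_denominator = _log_choose(N, n)
    for x in range(max(k, 0, n + K - N), min(n, K) + 1):
        total += math.exp(
            _log_choose(K, x) + _log_choose(N - K, n - x) - log_denominator
        )
    return min(1.0, total)


# -- Elim --------------------------------------------------------------------

def elim_oracle(
    study_members: dict[str, frozenset[str]],
    universe_members: dict[str, frozenset[str]],
    edges: list[tuple[str, str]],  # (parent, child) within the graph
    n: int,
    n_pop: int,
    alpha: float,
) -> dict[str, tuple[int, int, int, int]]:
    """Tables tested by the Elim procedure, recomputed from first principles.

    Terms are processed deepest-first (longest-path depth).  For each
    term, the elimination set is materialised from scratch as the union
    of the universe members of every *already significant strict
    descendant*, found by brute-force reachability.
    """
    terms = set(universe_members)
    depth = {t: 0 for t in terms}
    # longest path by relaxation until fixed point (small graphs only)
    changed = True
    while changed:
        changed = False
        for parent, child in edges:
            if depth[child] < depth[parent] + 1:
                depth[child] = depth[parent] + 1
                changed = True

    child_edges = [(p, c) for p, c in edges]
    significant: set[str] = set()
    tables: dict[str, tuple[int, int, int, int]] = {}
    for term in sorted(terms, key=lambda t: (-depth[t], t)):
        descendants = reachable(child_edges, term)
        eliminated: set[str] = set()
        for other in significant:
            if other in descendants:
                eliminated |= universe_members[other]
        k = len(study_members.get(term, frozenset()) - eliminated)
        big_k = len(universe_members[term] - eliminated)
        tables[term] = (k, n, big_k, n_pop)
        if hypergeom_tail_oracle(k, n, big_k, n_pop) <= alpha:
            significant.add(term)
    return tables


# -- DOT reading -------------------------------------------------------------

_NODE_RE = re.compile(r'^\s*"((?:[^"\\]|\\.)*)"\s*\[(.*)\];$')
_EDGE_RE = re.compile(
    r'^\s*"((?:[^"\\]|\\.)*)"\s*->\s*"((?:[^"\\]|\\.)*)"\s*\[(.*)\];$'
)


def _unescape(s: str) -> str:
    return s.replace('\\"', '"').replace("\\\\", "\\")


def parse_dot(text: str) -> tuple[set[str], dict[tuple[str, str], dict[str, str]]]:
    """Node ids and edge attribute maps of a DOT digraph."""
    nodes: set[str] = set()
    edges: dict[tuple[str, str], dict[str, str]] = {}
    for line in text.splitlines():
        edge_match = _EDGE_RE.match(line)
        if edge_match:
            a, b, attrs = edge_match.groups()
            attr_map = dict(
                re.findall(r'(\w+)="((?:[^"\\]|\\.)*)"', attrs)
            )
            edges[(_unescape(a), _unescape(b))] = attr_map
            continue
        node_match = _NODE_RE.match(line)
        if node_match:
            nodes.add(_unescape(node_match.group(1)))
    return nodes, edges
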