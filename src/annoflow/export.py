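"""DOT and TSV exports of annotation graphs and term statistics.

The DOT digraph mirrors the rendered annotation-flow convention: edges
point parent->child with pen width proportional to the number of proteins
flowing down the edge; directly annotated terms are filled and labelled
with the term name and occurrence, inherited-only terms are white and
unlabelled.  All output is deterministic (lexicographic ordering,
fixed number formatting) so repeated runs are byte-identical.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .enrichment import EnrichmentResult, bh_adjust
from .ontology import OntologyGraph
from .scoring import TermScore
from .sets import AnnotationGraph


class ExportError(ValueError):
    """Raised for inconsistent export inputs."""


@dataclass(frozen=True)
class RenderSpec:
    """Drawing parameters for DOT output."""

    min_penwidth: float = 1.0
    max_penwidth: float = 8.0
    direct_node_style: Mapping[str, str] = field(
        default_factory=lambda: {"style": "filled", "fillcolor": "lightgoldenrod1"}
    )
    inherited_node_style: Mapping[str, str] = field(
        default_factory=lambda: {"style": "filled", "fillcolor": "white"}
    )
    label_fields: tuple[str, ...] = ("name", "occurrence")

    def __post_init__(self) -> None:
        if self.min_penwidth > self.max_penwidth or self.min_penwidth <= 0:
            raise ExportError(
                f"invalid pen widths: {self.min_penwidth}..{self.max_penwidth}"
            )


def _dot_quote(value: str) -> str:
    return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _penwidth(flow: int, lo: int, hi: int, spec: RenderSpec) -> float:
    if hi == lo:
        return (spec.min_penwidth + spec.max_penwidth) / 2.0
    frac = (flow - lo) / (hi - lo)
    return spec.min_penwidth + frac * (spec.max_penwidth - spec.min_penwidth)


def export_dot(
    graph: AnnotationGraph,
    spec: RenderSpec | None = None,
    ontology: OntologyGraph | None = None,
) -> str:
    """Serialise an annotation graph as a Graphviz DOT digraph.

    Node labels use the ontology's term names when an ontology is given,
    otherwise the term ids.  Raises on an empty graph.
    """
    if not graph.nodes:
        raise ExportError("cannot export an empty graph")
    spec = spec or RenderSpec()
    flows = list(graph.flow_edges.values())
    lo, hi = (min(flows), max(flows)) if flows else (0, 0)

    lines = [f"digraph {_dot_quote(graph.set_name or 'annotation_graph')} {{"]
    lines.append("  rankdir=TB;")
    for term in sorted(graph.nodes):
        node = graph.nodes[term]
        if node.direct:
            style = dict(spec.direct_node_style)
            name = ontology.name_of(term) if ontology else term
            parts = []
            if "name" in spec.label_fields:
                parts.append(name)
            if "occurrence" in spec.label_fields:
                parts.append(f"({node.occurrence})")
            style["label"] = "\\n".join(parts)
        else:
            style = dict(spec.inherited_node_style)
            style["label"] = ""
        attrs = ", ".join(
            f"{key}={_dot_quote(str(val))}" for key, val in sorted(style.items())
        )
        lines.append(f"  {_dot_quote(term)} [{attrs}];")
    for (parent, child) in sorted(graph.flow_edges):
        flow = graph.flow_edges[(parent, child)]
        width = _penwidth(flow, lo, hi, spec)
        lines.append(
            f"  {_dot_quote(parent)} -> {_dot_quote(child)} "
            f"[penwidth={_dot_quote(f'{width:.3f}')}, "
            f"label={_dot_quote(str(flow))}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def format_p_value(p: float) -> str:
    """Scientific notation with 3 significant digits; underflow as '< eps'."""
    if p > 0.0:
        return f"{p:.3e}"
    tiny = sys.float_info.min * sys.float_info.epsilon  # smallest subnormal
    return f"< {tiny:.3e}"


def export_term_table(
    results: Mapping[str, EnrichmentResult],
    scores: Mapping[str, TermScore],
    graph: AnnotationGraph,
    ontology: OntologyGraph | None = None,
    bh_column: bool = False,
) -> str:
    """Term statistics TSV: term_id, name, occ, ic_score, p_value.

    Rows are sorted by p-value ascending, then ic_score descending, then
    term id; this places the most significant and, among those, the most
    specifically representative terms first.
    """
    missing = [t for t in graph.nodes if t not in results or t not in scores]
    if missing:
        raise ExportError(f"missing results/scores for terms: {sorted(missing)}")
    header = ["term_id", "name", "occ", "ic_score", "p_value"]
    adjusted: Mapping[str, float] = {}
    if bh_column:
        header.append("bh_p_value")
        adjusted = bh_adjust(results)
    rows = sorted(
        graph.nodes,
        key=lambda t: (results[t].p_value, -scores[t].ic_score, t),
    )
    lines = ["\t".join(header)]
    for term in rows:
        name = ontology.name_of(term) if ontology else term
        cells = [
            term,
            name,
            str(graph.nodes[term].occurrence),
            f"{scores[term].ic_score:.3f}",
            format_p_value(results[term].p_value),
        ]
        if bh_column:
            cells.append(format_p_value(adjusted[term]))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def export_protein_list(
    graph: AnnotationGraph,
    term_id: str,
    selection: Iterable[str] | None = None,
) -> str:
    """A node's member accessions as TSV, optionally restricted."""
    if term_id not in graph.nodes:
        raise ExportError(f"term {term_id!r} is not in the graph")
    members = graph.nodes[term_id].members
    if selection is None:
        chosen = members
    else:
        chosen = frozenset(selection)
        offenders = chosen - members
        if offenders:
            raise ExportError(
                f"selection contains non-members of {term_id}: {sorted(offenders)}"
            )
    return "\n".join(sorted(chosen)) + ("\n" if chosen else "")


def export_set_summary(summary: Mapping[str, object]) -> str:
    """Two-row TSV of the Set header statistics."""
    keys = list(summary)
    return (
        "\t".join(keys) + "\n" + "\t".join(str(summary[k]) for k in keys) + "\n"
    )
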