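"""GAF association reading and propagated corpus frequency tables.

The annotation corpus supplies two things to the rest of the package: the
direct accession->term map used to build per-Set annotation graphs, and
the propagated per-term accession counts that define each term's corpus
frequency for information-content scoring.  All counting is over distinct
accessions (a protein annotated twice to the same term, or reaching a
parent through two children, counts once), following the true path rule.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from .ontology import PROPAGATING, OntologyGraph

logger = logging.getLogger(__name__)

# GAF column 9 aspect letters for the canonical GO namespaces.
ASPECT_LETTERS = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}

_ISOFORM_SUFFIX = re.compile(r"-\d+$")

#: Minimum number of tab-separated columns for a usable GAF row
#: (through the aspect column).
_MIN_GAF_COLUMNS = 9


class CorpusError(ValueError):
    """Raised for corpus queries that cannot be answered."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One protein-to-term association from a GAF row."""

    accession: str
    term_id: str
    aspect: str | None  # GAF aspect letter, None if unrecognised
    evidence_code: str
    negated: bool = False


@dataclass
class AnnotationCorpus:
    """Direct annotation maps plus propagated per-term accession counts.

    ``direct_map[aspect][accession]`` is the set of directly annotated
    terms; ``propagated_count[term]`` the number of distinct accessions
    annotated to the term or any propagating descendant;
    ``corpus_size[aspect]`` the number of distinct accessions with at
    least one annotation in the aspect, and ``annotation_count[aspect]``
    the raw number of retained association records (used by the
    alternative information-content scaling convention).
    """

    ontology: OntologyGraph
    relations: frozenset[str] = PROPAGATING
    direct_map: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    propagated_count: dict[str, int] = field(default_factory=dict)
    corpus_size: dict[str, int] = field(default_factory=dict)
    annotation_count: dict[str, int] = field(default_factory=dict)
    dropped_records: int = 0
    _closure_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def term_closure(self, term_id: str) -> frozenset[str]:
        """The term plus all its propagating ancestors (cached)."""
        term = self.ontology.resolve(term_id)
        hit = self._closure_cache.get(term)
        if hit is None:
            hit = frozenset(
                self.ontology.ancestors(term, self.relations, include_self=True)
            )
            self._closure_cache[term] = hit
        return hit

    def annotated_terms(self, accession: str, aspect: str) -> frozenset[str]:
        """All terms annotating ``accession`` in ``aspect`` after propagation."""
        direct = self.direct_map.get(aspect, {}).get(accession)
        if not direct:
            return frozenset()
        out: set[str] = set()
        for term in direct:
            out |= self.term_closure(term)
        return frozenset(out)

    def accessions(self, aspect: str) -> frozenset[str]:
        return frozenset(self.direct_map.get(aspect, {}))


def parse_gaf(source: IO[str] | Iterable[str]) -> list[AnnotationRecord]:
    """Read GAF 2.x text into annotation records.

    Comment lines (leading ``!``) are ignored; rows with fewer columns
    than the aspect column are skipped and counted in a single warning.
    NOT-qualified rows are retained with the negation flag set so callers
    can decide their fate (all counting here excludes them).
    """
    records: list[AnnotationRecord] = []
    skipped = 0
    for line in source:
        line = line.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < _MIN_GAF_COLUMNS:
            skipped += 1
            continue
        qualifier = cols[3]
        negated = "NOT" in qualifier.split("|") if qualifier else False
        records.append(
            AnnotationRecord(
                accession=cols[1],
                term_id=cols[4],
                aspect=cols[8] if cols[8] in ASPECT_LETTERS else None,
                evidence_code=cols[6],
                negated=negated,
            )
        )
    if skipped:
        logger.warning("skipped %d malformed GAF rows", skipped)
    return records


def filter_evidence(
    records: Sequence[AnnotationRecord], excluded_codes: Iterable[str]
) -> list[AnnotationRecord]:
    """Drop records whose evidence code is in ``excluded_codes``."""
    excluded = frozenset(excluded_codes)
    if not excluded:
        return list(records)
    return [r for r in records if r.evidence_code not in excluded]


def build_corpus(
    records: Sequence[AnnotationRecord],
    ontology: OntologyGraph,
    relations: Iterable[str] = PROPAGATING,
    normalize_isoforms: bool = False,
) -> AnnotationCorpus:
    """Aggregate records into direct maps and propagated frequency counts.

    The aspect of each record is taken from the ontology (the GAF aspect
    letter cannot express synthetic namespaces); when the letter maps to a
    canonical GO namespace and disagrees with the ontology, the ontology
    wins with a warning.  Records referencing unknown terms, and
    NOT-qualified records, are dropped (counted in ``dropped_records``).
    """
    corpus = AnnotationCorpus(ontology=ontology, relations=frozenset(relations))
    direct: dict[str, dict[str, set[str]]] = {}
    annotation_count: dict[str, int] = {}

    for record in records:
        if record.negated:
            corpus.dropped_records += 1
            continue
        try:
            term = ontology.resolve(record.term_id)
        except Exception:
            logger.warning("record for unknown term %s dropped", record.term_id)
            corpus.dropped_records += 1
            continue
        aspect = ontology.aspect_of(term)
        letter_aspect = ASPECT_LETTERS.get(record.aspect or "", None)
        if letter_aspect is not None and letter_aspect != aspect:
            logger.warning(
                "record %s/%s claims aspect %s but the ontology says %s",
                record.accession, term, letter_aspect, aspect,
            )
        accession = record.accession
        if normalize_isoforms:
            accession = _ISOFORM_SUFFIX.sub("", accession)
        direct.setdefault(aspect, {}).setdefault(accession, set()).add(term)
        annotation_count[aspect] = annotation_count.get(aspect, 0) + 1

    corpus.direct_map = direct
    corpus.annotation_count = annotation_count
    corpus.corpus_size = {aspect: len(accs) for aspect, accs in direct.items()}

    counts: dict[str, set[str]] = {}
    for aspect, accs in direct.items():
        for accession in accs:
            for term in corpus.annotated_terms(accession, aspect):
                counts.setdefault(term, set()).add(accession)
    corpus.propagated_count = {term: len(accs) for term, accs in counts.items()}
    return corpus
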