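"""Synthetic ontologies, annotation corpora and Collections.

Every generator is a pure function of a :class:`FixtureSpec` (the seed
fully determines the output bytes) and returns both the flat-file text
and a manifest of the exact ground truth, so parsers and counters can be
checked against construction rather than against themselves.

A fixture emulates the study design the enrichment analysis targets: a
Collection holding a small study Set and a larger background Set drawn
from a common universe, with random direct annotations over a random
DAG, and optionally one *planted* term whose study and background
coverages are realised exactly (assigned to the first proteins of each
group, never sampled) so statistical power is sharp.  The default design
is a 20-protein study inside a 200-protein universe with the planted
term covering 80% of the study and 10% of the background.

Synthetic terms use a ``SYN:`` prefix and a synthetic namespace so they
cannot be mistaken for real GO accessions; GO-shaped ids are available
behind ``real_go_ids`` for format testing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np

from .corpus import ASPECT_LETTERS, AnnotationCorpus, build_corpus, parse_gaf
from .ontology import OntologyGraph, parse_obo
from .sets import Collection, ProteinSet, read_set_file

_LETTER_BY_ASPECT = {aspect: letter for letter, aspect in ASPECT_LETTERS.items()}


class FixtureError(ValueError):
    """Raised for infeasible fixture specifications."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study scenario."""

    n_terms: int = 25
    dag_density: float = 1.5  # expected parents per non-root term
    n_proteins: int = 200
    study_size: int = 20
    annotations_per_protein: float = 2.0  # mean direct annotations, >= 1
    planted_term: str | None = None
    study_coverage: float = 0.8
    background_coverage: float = 0.1
    seed: int = 0
    namespace: str = "synthetic_process"
    real_go_ids: bool = False
    evidence_codes: tuple[str, ...] = ("IEA", "IDA", "IMP")
    evidence_weights: tuple[float, ...] = (0.7, 0.2, 0.1)
    part_of_fraction: float = 0.0  # fraction of extra edges typed part_of

    def term_id(self, index: int) -> str:
        prefix = "GO" if self.real_go_ids else "SYN"
        return f"{prefix}:{index:07d}"

    def protein_id(self, index: int) -> str:
        return f"PROT{index:05d}"

    def with_planted(self, term_index: int | None = None) -> "FixtureSpec":
        """Convenience: plant the default enrichment scenario on a term.

        Defaults to the last-generated term, which by construction has no
        children, so the planted coverages are exactly the term's counts
        (no inherited contributions from descendants).
        """
        index = self.n_terms if term_index is None else term_index
        return replace(self, planted_term=self.term_id(index))

    def validate(self) -> None:
        if self.n_terms < 2:
            raise FixtureError("need at least 2 terms (root plus one child)")
        if self.dag_density < 1.0:
            raise FixtureError("dag_density below 1 cannot keep the DAG rooted")
        if self.n_proteins < self.study_size or self.study_size < 1:
            raise FixtureError("study must be a non-empty subset of the universe")
        if self.annotations_per_protein < 1.0:
            raise FixtureError("each protein needs at least one annotation on average")
        for fraction in (self.study_coverage, self.background_coverage):
            if not (0.0 <= fraction <= 1.0):
                raise FixtureError("coverage fractions must lie in [0, 1]")


def generate_ontology(spec: FixtureSpec) -> tuple[str, dict[str, Any]]:
    """A single-namespace OBO file with one root and random DAG edges."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    root = spec.term_id(1)
    edges: list[tuple[str, str, str]] = []
    for i in range(2, spec.n_terms + 1):
        term = spec.term_id(i)
        earlier = [spec.term_id(j) for j in range(1, i)]
        primary = earlier[int(rng.integers(len(earlier)))]
        edges.append((term, primary, "is_a"))
        n_extra = min(int(rng.poisson(spec.dag_density - 1.0)), len(earlier) - 1)
        if n_extra:
            pool = [t for t in earlier if t != primary]
            picks = rng.choice(len(pool), size=n_extra, replace=False)
            for p in sorted(picks):
                relation = (
                    "part_of"
                    if rng.random() < spec.part_of_fraction
                    else "is_a"
                )
                edges.append((term, pool[p], relation))

    stanzas = ["format-version: 1.2", "ontology: synthetic-fixture", ""]
    by_child: dict[str, list[tuple[str, str]]] = {}
    for child, parent, relation in edges:
        by_child.setdefault(child, []).append((parent, relation))
    for i in range(1, spec.n_terms + 1):
        term = spec.term_id(i)
        stanzas.append("[Term]")
        stanzas.append(f"id: {term}")
        stanzas.append(f"name: synthetic term {i}")
        stanzas.append(f"namespace: {spec.namespace}")
        for parent, relation in sorted(by_child.get(term, ())):
            if relation == "is_a":
                stanzas.append(f"is_a: {parent}")
            else:
                stanzas.append(f"relationship: {relation} {parent}")
        stanzas.append("")
    obo_text = "\n".join(stanzas)
    manifest = {
        "root": root,
        "terms": [spec.term_id(i) for i in range(1, spec.n_terms + 1)],
        "edges": sorted(edges),
    }
    return obo_text, manifest


def generate_corpus(
    spec: FixtureSpec, ontology: OntologyGraph
) -> tuple[str, dict[str, Any]]:
    """A GAF 2.2 corpus over ``ontology`` with optional planted coverage.

    Non-planted annotations are sampled uniformly over the non-root
    terms (the planted term is excluded from the random pool so its
    coverages hold exactly).
    """
    spec.validate()
    if spec.planted_term is not None and spec.planted_term not in ontology:
        raise FixtureError(f"planted term {spec.planted_term!r} not in the ontology")
    rng = np.random.default_rng(spec.seed + 1)
    root = ontology.roots[spec.namespace]
    pool = sorted(t for t in ontology.terms if t != root and t != spec.planted_term)
    if not pool:
        raise FixtureError("no non-root terms available for random annotation")
    weights = np.asarray(spec.evidence_weights, dtype=float)
    weights = weights / weights.sum()

    records: list[tuple[str, str, str]] = []
    proteins = [spec.protein_id(i) for i in range(spec.n_proteins)]
    for protein in proteins:
        n_annot = max(1, int(rng.poisson(spec.annotations_per_protein)))
        n_annot = min(n_annot, len(pool))
        picks = rng.choice(len(pool), size=n_annot, replace=False)
        for p in sorted(picks):
            evidence = spec.evidence_codes[
                int(rng.choice(len(weights), p=weights))
            ]
            records.append((protein, pool[p], evidence))

    planted_truth: dict[str, Any] = {}
    if spec.planted_term is not None:
        study = proteins[: spec.study_size]
        background = proteins[spec.study_size:]
        n_study = round(spec.study_coverage * len(study))
        n_background = round(spec.background_coverage * len(background))
        carriers = study[:n_study] + background[:n_background]
        for protein in carriers:
            records.append((protein, spec.planted_term, spec.evidence_codes[0]))
        planted_truth = {
            "term": spec.planted_term,
            "study_carriers": n_study,
            "background_carriers": n_background,
        }

    records.sort()
    letter = _LETTER_BY_ASPECT.get(spec.namespace, "S")
    lines = ["!gaf-version: 2.2"]
    for protein, term, evidence in records:
        lines.append(
            "\t".join(
                [
                    "AF", protein, protein, "", term, "AF_REF:0000001",
                    evidence, "", letter, "", "", "protein",
                    "taxon:0000", "20150320", "AF", "", "",
                ]
            )
        )
    gaf_text = "\n".join(lines) + "\n"
    manifest = {
        "records": records,
        "proteins": proteins,
        "planted": planted_truth,
    }
    return gaf_text, manifest


def generate_collection(spec: FixtureSpec) -> tuple[dict[str, str], dict[str, Any]]:
    """Study and background Set files (disjoint) forming one Collection."""
    spec.validate()
    proteins = [spec.protein_id(i) for i in range(spec.n_proteins)]
    study = proteins[: spec.study_size]
    background = proteins[spec.study_size:]
    files = {
        "study.txt": "\n".join(study) + "\n",
        "background.txt": "\n".join(background) + "\n",
    }
    manifest = {
        "collection": "fixture",
        "sets": {"study": study, "background": background},
    }
    return files, manifest


def write_fixture_dir(spec: FixtureSpec, path: str | Path) -> Path:
    """Materialise a self-contained fixture directory.

    Layout: ontology.obo, corpus.gaf, sets/*.txt plus a TSV manifest of
    every edge, record and membership.
    """
    path = Path(path)
    (path / "sets").mkdir(parents=True, exist_ok=True)
    obo_text, onto_manifest = generate_ontology(spec)
    ontology = parse_obo(io.StringIO(obo_text))
    gaf_text, corpus_manifest = generate_corpus(spec, ontology)
    files, collection_manifest = generate_collection(spec)

    (path / "ontology.obo").write_text(obo_text)
    (path / "corpus.gaf").write_text(gaf_text)
    for name, text in files.items():
        (path / "sets" / name).write_text(text)

    rows = [["kind", "a", "b", "c"]]
    for child, parent, relation in onto_manifest["edges"]:
        rows.append(["edge", child, parent, relation])
    for protein, term, evidence in corpus_manifest["records"]:
        rows.append(["record", protein, term, evidence])
    for set_name, members in collection_manifest["sets"].items():
        for accession in members:
            rows.append(["member", set_name, accession, ""])
    if corpus_manifest["planted"]:
        planted = corpus_manifest["planted"]
        rows.append(
            [
                "planted",
                planted["term"],
                str(planted["study_carriers"]),
                str(planted["background_carriers"]),
            ]
        )
    (path / "manifest.tsv").write_text(
        "\n".join("\t".join(row) for row in rows) + "\n"
    )
    return path


@dataclass
class FixtureBundle:
    """Parsed, analysis-ready objects built from one spec."""

    spec: FixtureSpec
    ontology: OntologyGraph
    corpus: AnnotationCorpus
    collection: Collection
    study: ProteinSet
    manifests: dict[str, Any] = field(default_factory=dict)


def build_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate and parse a complete fixture in memory."""
    obo_text, onto_manifest = generate_ontology(spec)
    ontology = parse_obo(io.StringIO(obo_text))
    gaf_text, corpus_manifest = generate_corpus(spec, ontology)
    corpus = build_corpus(parse_gaf(io.StringIO(gaf_text)), ontology)
    files, collection_manifest = generate_collection(spec)
    collection = Collection(name="fixture")
    for name, text in files.items():
        collection.add(
            read_set_file(io.StringIO(text), name.removesuffix(".txt"), "fixture")
        )
    return FixtureBundle(
        spec=spec,
        ontology=ontology,
        corpus=corpus,
        collection=collection,
        study=collection.sets["study"],
        manifests={
            "ontology": onto_manifest,
            "corpus": corpus_manifest,
            "collection": collection_manifest,
        },
    )
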