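# annoflow

Annotation-flow graphs, enrichment statistics and information-content
scores for protein sets annotated with ontology terms.

## The problem

Groups of supposedly similar proteins — a curated enzyme family, a
protein complex, a list of differentially expressed gene products — are
rarely annotated evenly. Some members carry deep, specific Gene
Ontology (GO) annotations; others stop at generic terms or carry none at
all. That heterogeneity makes it hard to judge how functionally
coherent a set really is, and where annotation could be extended.

`annoflow` addresses this by turning a protein Set's annotations into an
*annotation flow graph*: the sub-DAG of the GO aspect induced by every
term the Set touches, with edges drawn parent→child and weighted by how
many Set proteins "flow down" from the general term into the more
specific one. On top of the graph it computes, per term:

- **occurrence** — the number of Set proteins annotated to the term or
  any descendant (the true path rule: an annotation to a term implies
  annotation to every ancestor);
- **Fisher exact enrichment p-value** of the study Set against its
  Collection background, with an optional topology-based **Elim**
  correction that removes proteins already explained by significantly
  enriched descendant terms before testing their ancestors;
- **IC-based term score** `ICscore(t) = (IC(t)/log2 N) · s(t)`, where
  `IC(t) = −log2 f(t)` is the term's information content in the
  annotation corpus (`f(t)` the fraction of corpus proteins annotated to
  `t` or a descendant, `N` the number of annotated corpus proteins in
  the aspect) and `s(t)` the term's annotation frequency within the Set.
  High scores mark terms that are both *specific* and *common in the
  Set* — good pivot points for annotation extension.

Any non-leaf node of a graph can be used to **re-root** the analysis:
the view shrinks to that term's branch, enrichment is recomputed over
the restricted universe, while IC scores stay identical by construction.

Inputs are the standard flat formats: an OBO ontology, a GAF 2.x
association file (with per-evidence-code filtering, e.g. dropping IEA),
and plain-text protein Sets grouped into a Collection that defines the
enrichment background. Outputs are Graphviz DOT graphs and TSV tables.

## Worked example

A fully synthetic study ships with the package: 200 proteins annotated
over a random 25-term DAG, split into a 20-protein study Set and a
180-protein background Set, with one term planted to cover 80% of the
study but only 10% of the background.

```bash
annoflow fixture --out demo/fx --seed 7
annoflow analyze --obo demo/fx/ontology.obo --gaf demo/fx/corpus.gaf \
    --sets-dir demo/fx/sets --aspect synthetic_process --out demo/run
head -3 demo/run/study.summary.tsv demo/run/study.terms.tsv
```

prints

```
set     aspect             root_term    set_size  annotated_in_set  n_terms
study   synthetic_process  SYN:0000001  20        20                24

term_id      name               occ  ic_score  p_value
SYN:0000025  synthetic term 25  16   0.268     4.277e-11
SYN:0000010  synthetic term 10  3    0.067     2.915e-01
```

The planted term `SYN:0000025` tops the table: 16 of the 20 study
proteins carry it (occurrence), its p-value of 4.3 × 10⁻¹¹ reflects how
unlikely 16-of-20 is for a term covering only 34 of 200 universe
proteins, and its IC score 0.268 is the product of its scaled corpus
specificity and its 16/20 study frequency. `demo/run/study.graph.dot`
holds the flow graph (render it with any Graphviz viewer); re-rooting at
any listed non-leaf term re-derives the focused view:

```bash
annoflow reroot --run-dir demo/run --term SYN:0000002
```

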