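# Methods

## Model and procedure

`annoflow` analyses a *study Set* of protein accessions inside a
*Collection* whose union of Sets defines the background universe. For a
chosen ontology aspect it:

1. propagates each protein's direct GAF annotations up the ontology DAG
   over the propagating relations (true path rule), producing per-term
   member sets;
2. induces the annotation flow graph: one node per term with at least
   one Set member, edges parent→child weighted by the number of shared
   members (since members propagate upward, a child's members are a
   subset of its parent's, so the edge weight equals the child's
   occurrence whenever the DAG edge is the child's only retained path);
3. tests every node with the one-sided Fisher exact test
   `P(X ≥ k)` for `X ~ Hypergeom(N_pop, K, n)`, where `k`/`n` count the
   study and `K`/`N_pop` the universe — optionally after Elim
   decorrelation;
4. scores every node with `ICscore(t) = ICu(t)·s(t)`,
   `ICu(t) = −log2 f(t) / log2 N`.

### Assumptions

- Under the null, the study Set is an exchangeable random draw from the
  Collection universe: the hypergeometric law is exact, not asymptotic.
- Annotations are taken at face value; NOT-qualified GAF rows are
  excluded from all counting, and annotation counting is always over
  distinct accessions, never association rows.
- The supplied GAF *is* the IC reference corpus. IC values therefore
  depend on corpus choice; scores from different corpora are not
  comparable.

## Elim decorrelation

Because counts propagate, a term's test is positively dependent on all
its descendants'. Elim processes the graph level by level (node depth =
longest path from the root; deepest level first; lexicographic order
inside a level — the published procedure leaves tie order open, so a
deterministic rule was fixed). A term significant at `elim_alpha`
(default 0.05) marks its universe members for elimination from the term
counts (`k` and `K`) of all its ancestors; the margins `n` and `N_pop`
stay fixed. Eliminations apply only to strictly shallower levels, so
same-level terms never affect each other. `elim_alpha` is independent
of the reporting significance level: the internal threshold shapes the
elimination cascade, the reporting α only labels output. Elim p-values
are conditioned on descendants and are not amenable to standard
multiple-testing correction; the optional Benjamini–Hochberg column
(`--bh`) is exploratory only and labelled non-canonical.

## Re-rooting

Re-rooting at a non-leaf node restricts the view to that term and its
retained descendants. The Set stays whole (`set_size` unchanged), node
member sets are unchanged (they were already subsets of the new root's
members), and enrichment is recomputed over the *view*: the universe
shrinks to Collection proteins annotated under the new root, the study
to its members there, and only view terms are tested. The IC term score
is invariant under re-rooting: both factors — corpus frequency and
within-Set frequency — are view-independent. To make the invariance
exact, the `s(t)` denominator is the Set's aspect-level annotated count
(`set_annotated`), which survives re-rooting, not the view's coverage.

## Parameters

| parameter | default | meaning |
|---|---|---|
| propagating relations | `is_a`, `part_of` | edges that carry annotations; `regulates` kept in the graph but non-propagating (standard GO practice). Configurable. |
| `elim_alpha` | 0.05 | internal Elim significance level |
| reporting α | 0.05 | labels significant rows; no effect on computation |
| `n_mode` | `proteins` | `N` in the IC scaling = distinct annotated corpus proteins in the aspect, so a single-protein term attains `ICu = 1` and the scale is exactly [0, 1]; `annotations` counts association rows instead |
| `s_denominator` | `annotated` | `s(t)` divides by the Set's annotated protein count; `set_size` divides by the whole Set |
| background mode | `rest` | the study-vs-remaining-Sets and whole-Collection-population phrasings parameterise the same 2×2 table (`k`, `n`, `K`, `N_pop` determine it fully); both flag values are accepted and equivalent |
| `annotated_only` | off | universe proteins with no annotation in the aspect count in `N_pop` by default (they are genuine trial units); the flag drops them from both margins |
| pen widths | 1.0–8.0 | DOT edge widths, linear in flow count between the observed minimum and maximum; constant-flow graphs use the midpoint (the rendering convention says only "proportional", so linear was chosen and documented) |

## Numerical choices

- Fisher tails come from `scipy.stats.hypergeom.sf`; values are clipped
  into [0, 1]. Degenerate tables (`n = 0` or `K = 0`) return 1 by
  convention.
- Logarithms are base 2 throughout; `ICu` is clipped into [0, 1].
- Term tables sort by p-value ascending, then IC score descending, then
  term id — a deterministic total order.
- P-values that underflow to 0 are printed as `< ε` (ε the smallest
  subnormal double) in text output.
- All exports are byte-deterministic: lexicographic node/edge ordering,
  fixed decimal formats (scores to 3 decimals, p-values to 3 significant
  digits).

## Synthetic data

The fixture generator emulates the target study design: a random rooted
DAG (each later term takes one uniform parent among earlier terms plus
Poisson-distributed extra parents), proteins with Poisson-distributed
direct annotations sampled uniformly over non-root terms, and a
two-Set Collection (disjoint study and background). The default
scenario — 25 terms, 200 proteins, 20-protein study, planted term
covering 80% of the study versus 10% of the background — is the
configuration under which power and calibration are assessed. Planted
memberships are assigned deterministically to the first proteins of
each group rather than sampled, so the realised coverages are exact and
power statements are sharp; the planted term is excluded from the
random annotation pool for the same reason, and defaults to the last
generated term, which is childless by construction.

What the generator does **not** emulate: the real GO's depth and fan-out
(thousands of terms, highly uneven branching), realistic annotation
depth profiles, evidence-code correlation with term specificity, or
inter-protein annotation correlation within families. Passing tests
therefore demonstrate correctness of the propagation, testing and
scoring machinery under exchangeable annotations — not that any
particular biological corpus satisfies those assumptions.

Problem sizes used by the test suite and the acceptance script (random
tables ≤ 60 trials, fixtures ≤ 40 terms and ≤ 200 proteins, 200 power
replicates, 2000 null replicates) were chosen so every oracle can be
brute-force and exact while the whole characterisation completes in
seconds.

## Design notes

- Fisher calibration: the test is discrete, so its achievable size at
  α = 0.05 is strictly below 0.05 by an amount set by the hypergeometric
  support. Calibration checks compare the empirical rejection rate to
  the analytically computed size `P(p ≤ α | null)` rather than to the
  nominal α.
- The OBO reader is built on `obonet`; alias (`alt_id`) resolution,
  obsolete-term handling (`replaced_by` remapping behind a flag), root
  detection and cycle diagnosis are layered on top. A cyclic `is_a`
  structure is a hard error naming one cycle; multiple roots per aspect
  are an error, never a silent pick.
- The GAF reader is a small line parser because row-level
  skip-and-count tolerance of malformed input is part of the contract.
  The aspect of a record is resolved from the ontology term's namespace
  (the GAF aspect letter cannot express synthetic namespaces and is
  only cross-checked for the three canonical ones).
- Accessions are opaque case-sensitive strings; isoform suffixes
  (`-1`) are distinct identifiers unless `normalize_isoforms` strips
  them. The corpus GAF defines the identifier namespace; no mapping
  services are involved.

## Known limitations

- Cross-aspect relationships are ignored; each analysis runs within one
  aspect.
- No GSEA-style or permutation-based testing; the only statistics are
  the Fisher/Elim p-values and the IC score.
- Very large graphs (thousands of nodes) export fine but are not laid
  out or simplified; re-rooting is the intended navigation aid.
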