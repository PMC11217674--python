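# Methods

This note documents the models and procedures behind `funcdeval`, the
choices made where several defensible readings exist, and what the synthetic
test bed does and does not establish about real annotation data.

## The evaluation problem

A function-prediction method emits, per protein, a set of GO terms with
method-specific confidence scores. Judging such output against reference
annotations (e.g. GOA/UniProt) is not a plain set-matching problem: GO terms
live in a directed acyclic graph (child → parent = specific → general), so a
prediction can be wrong-but-near (a parent of the annotated term), right at
a different granularity (a distant ancestor), or simply in another branch.
`funcdeval` quantifies prediction quality along five complementary axes:
DAG-aware precision classes, term specificity (information content),
semantic similarity, two-sided coverage, and recovery of enrichment results
on gene lists.

## Ontology handling

The ontology is parsed from OBO 1.2 (go-basic dialect) via `obonet` into a
typed multigraph. Closure queries (ancestors, descendants, depth,
true-path propagation) follow a configurable relation set, default
`{is_a, part_of}` — the convention of go-basic tooling; `regulates`-family
edges are retained in the graph but excluded from closures unless
requested.

**Depth** is the *minimum* number of traversal edges from a term to its
namespace root (`depth(root) = 0`). Where a term has several routes to the
root, the shortest is used: "number of jumps to the root" is read as the
minimal jump count. The near-root filter (`filter_by_depth`, default
`min_depth = 3`) drops predictions fewer than three edges from the root,
the standard guard against methods that annotate everything at or near the
root.

Alt-ids resolve silently to canonical ids; obsolete terms and ids unknown
to the loaded release are dropped from annotation/prediction inputs with a
logged count rather than failing (release skew between GOA and go-basic is
routine). Cross-namespace terms inside a namespace set are an error, not a
warning: they indicate corrupted input rather than skew.

## Precision classes

Each prediction receives exactly one of four classes relative to the
protein's annotated terms in the same namespace:

* **HIT** — the predicted term is annotated;
* **Close** — it is a direct parent or child of an annotated term;
* **Related** — it is an ancestor or descendant at graph distance ≥ 2;
* **Unrelated** — none of the above.

Two choices make the classes a partition (so frequencies sum to 1):

1. With multiple annotated terms, the *most favourable* relation wins
   (HIT > Close > Related > Unrelated). The precedence is deterministic and
   order-free; a prediction Close to one annotated term but identical to
   another is a HIT.
2. "Related" explicitly excludes distance-1 relatives, which belong to
   Close. Since parents are also ancestors, Related is operationally
   "in the ancestor/descendant closure but not a direct neighbour".

Proteins with no reference annotation in a namespace cannot be judged;
their predictions are excluded from the frequencies and reported as a
separate `unevaluable` count, never folded into Unrelated.

## Information content

Term specificity is computed as

    IC(t) = −log₂ p(t),   p(t) = 1 − child_count(t) / (child_count(t) + ancestor_count(t))

in bits. Two counting strategies are shipped because the quantity can be
read against a corpus or against the bare graph:

* `descendant_protein_counts` (default): after true-path propagation of the
  reference corpus, `child_count(t)` is the number of (protein, term)
  annotations on `t` or any proper descendant, `ancestor_count(t)` the
  number on proper ancestors.
* `term_graph_counts`: `child_count(t) = |descendants(t)|`,
  `ancestor_count(t) = |ancestors(t)|`; the corpus is ignored.

The strategy is recorded in all outputs. Note the formula's orientation as
printed: a namespace root has `ancestor_count = 0`, hence `p = 0` and
`IC = +∞` (reported as an infinity sentinel, excluded from means but
counted), while a deep term with nothing annotated at or below it has
`p = 1` and `IC = 0`. This gives *high* IC to root-like terms and *low* IC
to rare specific ones — the opposite of the usual "rarer = more
informative" reading of corpus IC. The formula is implemented verbatim and
the tension documented here rather than silently corrected; an optional
add-one smoothing (off by default) removes the boundary cases without
changing the orientation. p and IC are undefined (flagged `None`) when both
counts are zero.

## Wang similarity and BMA

Term-level similarity uses the Wang graph method. For a term A, every
ancestor t gets an S-value: `S_A(A) = 1` and
`S_A(t) = max over in-DAG children c of w(c→t) · S_A(c)`, with contribution
factors `w(is_a) = 0.8`, `w(part_of) = 0.6` (the customary defaults of
Wang-method implementations, made explicit and configurable here). Then

    sim(A, B) = Σ_{t ∈ DAG_A ∩ DAG_B} (S_A(t) + S_B(t)) / (SV(A) + SV(B)),

symmetric, in [0, 1], with `sim(A, A) = 1`. Parallel edges between a term
pair take the larger factor. Set-level similarity is the best-match
average: the mean of all row maxima and all column maxima of the pairwise
matrix. Per-protein SS is the BMA between the predicted and annotated term
sets of one namespace.

Similarity between a non-empty and an empty set is **undefined** and
reported as missing, never 0: coercing to 0 would silently deflate
averages for sparsely annotated proteins. The implementation (topological
dynamic programming) is cross-checked in the tests against an independent
brute-force implementation that maximises edge-weight products over all
explicitly enumerated paths; the two agree to 1e-9 on seeded random DAGs.

## Score stratification

Each (method, namespace) stratum's scores are cut at their empirical
25/50/75% quantiles using linear interpolation of order statistics (the
default quantile definition of the R `quantile` function, type 7). The four
groups are cumulative — all records, top 75%, top 50%, top 25% — and
records exactly at a cutoff are retained (≥), so ties can push a group
slightly above its nominal fraction; this is deterministic and recorded in
the output metadata. Groups are nested by construction, and per-group
metrics (median per-protein SS, IC summary, distinct-protein count) show
what survives as the confidence threshold rises. Quantiles are computed per
(method, namespace) independently; scores are never compared across
methods, whose scales are not commensurable.

## Two-sided coverage

Per (protein, method, namespace), coverage is reported at three cumulative
levels — `guessed` (HIT only), `at_least_close` (+Close),
`at_least_related` (+Related) — on both sides of the comparison:

* prediction side: the fraction of predicted terms achieving the level
  against the annotation set ("how much of what was said is right");
* annotation side: the fraction of annotated terms for which *some*
  prediction achieves the level, evaluated with the same relation logic in
  the symmetric direction ("how much of what could be said was said").

A protein with annotations but no predictions has an undefined prediction
side (NaN) and 0 on the annotation side; a protein with no annotations is
unevaluable and excluded. Aggregates are means over evaluable proteins
(pooled-term aggregation can be derived from the per-protein table).

## Enrichment and recovery

Over-representation of each term in a study gene list against a universe
is tested with the one-sided Fisher's exact test (exact hypergeometric
tail, via `scipy.stats.hypergeom`). Gene annotations are true-path
propagated before testing; universe genes without any term stay in the
population denominator. Alongside the classic per-term p-value, the `elim`
procedure runs bottom-up (decreasing DAG depth, lexicographic tie-break):
when a term's current-set p-value falls below the elimination cutoff
(default 0.01, the customary default of the algorithm's reference
implementation), its genes are removed from all ancestors before those are
tested. Setting the cutoff to 0 disables elimination, and the elim
p-values then equal the classic ones bitwise. Significance is flagged from
the *classic* p-value at α = 0.05 with no multiple-testing correction by
default (an optional Benjamini–Hochberg flag exists); both p-values are
always reported so either convention is recoverable downstream.

The recovery stage runs enrichment twice per namespace — once on
reference-derived gene annotations, once on prediction-derived ones
(protein scores transferred to genes by the max rule, restricted to each
cumulative score-quantile group) — and reports the BMA Wang similarity
between the two significant-term sets, missing (not 0) when either set is
empty, plus the number of study genes still carrying a significant term.
"Genes with significant terms" counts study genes only.

## Synthetic data: what it emulates

The generator produces every input with recorded ground truth, all
randomness flowing from one seeded generator:

* **DAG** — layered, single root per namespace, widths growing by
  `mean_children` (default 2.5) over `n_levels` (default 6) to `n_terms`
  (default 500); each non-root term has one parent in the previous level
  plus an extra parent from any shallower level with probability 0.2;
  edges are `part_of` with probability 0.15, else `is_a`. Acyclic by
  construction and exhaustively re-checked in tests.
* **Corpus** — per protein a Poisson number (mean 3) of annotations on
  terms drawn with weight `depth_bias^depth` (default 1.6, leaf-biased);
  proteins grouped into genes with `1 + Poisson(isoform_mean − 1)`
  isoforms.
* **Predictions** — per record, a true (protein, term) annotation is
  sampled and an intended class drawn from the mixture
  π = (0.4, 0.3, 0.2, 0.1) over HIT/Close/Related/Unrelated; the term is
  placed uniformly in the corresponding DAG pool. If a pool is empty the
  class falls forward through Close → Related → Unrelated, then back
  toward better classes (a root term, from which everything descends, has
  no Unrelated pool). The *realized* class — the best relation against
  the protein's full annotation set, which can beat the intended one when
  placements collide with a second annotation — is recorded as ground
  truth, and the score is drawn from that class's Beta distribution
  (HIT Beta(8,2), Close Beta(5,3), Related Beta(3,3), Unrelated
  Beta(2,5)): overlapping supports, higher means for better classes, so
  stratification is informative but not degenerate.
* **DEG lists** — a study of 50 genes drawn without replacement from a
  1000-gene universe with weight θ = 9 for carriers of a target term
  (chosen as the term whose propagated carrier frequency is closest to
  10% when not supplied), weight 1 otherwise.

What passing tests on this bed establish: the graph algorithms, the
classifier, the similarity and enrichment machinery are internally correct
against independent oracles, and the pipeline's qualitative behaviours
(SS rising with score cutoffs, planted signal recovered, elim damping
inherited significance) emerge under controlled conditions. What it does
*not* establish: performance on real ontologies (the generator mimics GO's
scale and shape, not its term semantics, annotation biases, or evidence
codes), realistic score calibration, or the behaviour of any specific
prediction method.

## Numerical and design notes

* Domain-hit filtering: "alignment coverage" is computed on profile (HMM)
  coordinates relative to profile length — the standard reading for
  domain-completeness filtering; i-Evalue ≤ 1e-3 and coverage ≥ 0.70 are
  hard thresholds, then overlaps on protein coordinates (≥ 1 shared
  residue, 1-based inclusive) are resolved greedily longest-first with
  deterministic tie-breaks (smaller i-Evalue, then accession). Greedy
  choice matches exhaustive search whenever at most one hit can survive;
  with several compatible hits it prefers long alignments over maximum
  count, which is the desired behaviour for domain architecture.
* The profile-baseline score is −log₁₀(i-Evalue), capped at 300 to keep
  scores finite when HMMER reports an underflowed 0.
* The null-calibration check of the exact test uses a term carried by 30%
  of the universe: an exact test's achievable size is quantised, and at
  low carrier counts it sits far below the nominal 0.05 (e.g. 0.021 at
  10% membership with a 50-gene study), which would make an empirical
  two-sided check around 0.05 meaningless. At 30% membership the
  achievable size is 0.0435 and the measured rejection rate over 500 null
  replicates falls inside the 95% binomial envelope.
* Degenerate inputs: empty annotation sets are "unevaluable" (classifier)
  or "undefined" (similarity), never zero; all-identical scores collapse
  the four quantile groups into one (allowed and logged); an empty DEG
  list is a validation error.
* Problem sizes in the test suite and acceptance script — 200–500-term
  DAGs, 300–500-protein corpora, 10⁴ predictions, 500 null replicates,
  100 power replicates — were chosen so each contract is exercised at
  the scale where its statistical assertions are sharp while the whole
  suite completes in well under a minute per module.

## Known limitations

* OWL, cross-ontology links and GO release diffing are out of scope; the
  parser handles the go-basic OBO dialect.
* The IC formula's orientation (see above) is reported as printed; users
  wanting conventional corpus IC (−log₂ frequency) should treat the IC
  module's output accordingly.
* GAF writing uses a fixed evidence code (IEA) and is intended for
  round-tripping synthetic corpora, not for producing submission-grade
  association files.
* CAFA-style information-accretion metrics (Fmax, Smin) are deliberately
  not implemented.
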