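# Methods

This note documents the models and procedures implemented in `annokit`,
the parameter choices that matter, what the synthetic data emulates, and
the numerical decisions a maintainer would want written down.

## Versioned data resolution

A dataset is a file identified by `(name, version)` where the version is
an ISO-8601 date, with a SHA-256 content digest recorded at registration.
A *release manifest* maps tool names to pinned `(name, version)` pairs.
Resolution is a pure lookup: identical `(tool, release)` always returns
the identical descriptor, so a pipeline run under a fixed release on
fixed data is byte-reproducible. Design choices:

- **One manifest per release.** Partial updates (some datasets newer
  than others) are expressed by what the manifest pins, not by
  sub-release labels.
- **Overrides are logged.** A user-supplied file is returned verbatim
  but a provenance entry records the substitution; reproducibility
  audits need the trail, not a prohibition.
- **Serialization is human-diffable** (YAML index plus one manifest file
  per release) so two releases can be compared with `diff`.

## The table contract

Tables are strict TSV: header row, TAB as the only delimiter, no quoting
dialect (cells may not contain tabs or newlines), `#`-prefixed lines
skipped, cells treated as uninterpreted text. `annotate` appends columns:
each input row emits `max(1, hits)` output rows, input cells
byte-identical in every emitted row, hits in the order the annotator
returned them (hit order is an implementation decision here; upstream
data sources generally do not define one). Zero hits keep the row padded
with the missing token (`NA` by default) — dropping unmatched rows is
available behind a flag but is not the default, because downstream joins
usually need the full entity list. The row-count law (output rows equal
the sum over input rows of `max(1, hits)`) is the invariant every
chained pipeline's bookkeeping relies on.

## Linkage disequilibrium

From haplotype counts (n₁₁, n₁₂, n₂₁, n₂₂) for allele pairs
(A,B), (A,b), (a,B), (a,b):

    pA = (n11+n12)/n,  pB = (n11+n21)/n,  p11 = n11/n
    D  = p11 − pA·pB
    D′ = |D| / Dmax,   Dmax = min(pA(1−pB), (1−pA)pB)      if D > 0
                       Dmax = min(pA·pB, (1−pA)(1−pB))     if D < 0
    r² = D² / (pA(1−pA)·pB(1−pB))

All arithmetic uses exact rationals (`fractions.Fraction`) until the
final float conversion, so 0 ≤ r² ≤ D′ ≤ 1 and "a zero cell implies
D′ = 1" hold identically, not merely to rounding. A monomorphic locus
(pA or pB ∈ {0, 1}) raises a typed error instead of returning 0: "no
disequilibrium" and "not computable" are different facts. Estimating
haplotypes from genotypes (EM) is out of scope; counts enter from
precomputed sources.

## Coordinates, blocks, liftover

All internal coordinates are 1-based fully closed intervals (the
Ensembl convention); BED-dialect input is converted at the reader.
Overlap requires ≥ 1 shared base — adjacency does not count — and is
strand-agnostic, since the block-to-gene step of a GWAS annotation is.
Block assignment returns distance 0 on containment, otherwise the
distance to the nearer boundary; ties break to the lower start
coordinate, and assignment never crosses chromosomes (both decisions are
ours; upstream definitions of "closest" are silent). Liftover uses
non-overlapping source intervals each carrying a target chromosome and
additive offset — deliberately simpler than chain-file alignment
liftover, which is out of scope; overlapping intervals are rejected at
load time, and unmapped positions are a typed outcome, not an error.

## Enrichment statistics

With a background of N objects of which K are annotated (after
true-path propagation) to a term, and a study subset of n objects with k
annotated, the null law of k is Hypergeometric(N, K, n).

- over-representation: P(X ≥ k); under-representation: P(X ≤ k);
- two-sided: the point-probability (minimum-likelihood) method — sum of
  P(X = i) over all i with P(X = i) ≤ P(X = k), the convention of
  standard exact-test implementations (verified in tests against the 2×2
  Fisher exact p-value). Point probabilities are compared with relative
  slack 1e−7 so float noise cannot split exact pmf ties.
- Multiple testing: Benjamini–Hochberg step-up, delegated to
  statsmodels behind the `bh_adjust` surface and checked against the
  direct definition in tests. m is the number of testable terms — those
  with K ≥ 1 in the background, per namespace; including never-testable
  terms would deflate the FDR.
- Identifiers absent from the corpus are dropped from both study and
  background and reported in the outcome; symbol loss between data
  versions is expected and must be visible.
- Annotation evidence codes are not filtered (a hook exists at the
  association-reading step).
- `part_of` edges propagate like `is_a` by default; configurable at OBO
  load.

Exact tests are discretely conservative: each term's attainable
p-values are a finite set, so the achieved size at α = 0.05 is below
0.05, more markedly for terms with small K, and terms annotated to the
whole background (K = N) can never reject. On the synthetic corpus used
for calibration (200 genes, 50 terms, Poisson(3) direct annotations,
study size 40) the pooled null rejection rate measures ≈ 0.032 — the
expected behaviour of an exact test, not an implementation artifact.
Study size 40 of a 200-gene background was chosen as a realistic
differential-expression study fraction.

## Information content and functional similarity

IC(t) = −ln(count(t)/count(root)) per namespace, with propagated counts;
the denominator is the root count (number of objects annotated anywhere
in the namespace), and terms with zero count carry no IC. Natural
logarithm throughout. Term similarity is MICA-based: Resnik = IC(MICA),
Lin = 2·IC(MICA)/(IC(t₁)+IC(t₂)) (defined as 0 when both ICs are 0),
Rel = Lin·(1 − e^{−IC(MICA)}) — the last factor is 1 − p(MICA),
computed from the IC table to avoid a second probability table.
Gene-level similarity evaluates the term-pair matrix over the two genes'
**direct** annotation sets while IC uses **propagated** counts — the
standard convention of this method family — and combines by best-match
average or maximum. An object with no usable terms is a typed error.
A note on monotonicity: adding an annotated object to the corpus lowers
the IC of the terms covering it (numerator and root denominator both
grow), but *raises* the IC of every other term, whose probability mass
shrinks; only the first direction is a law and only it is asserted.

Composite cross-namespace scores (e.g. combining BP and MF into one
funSim value) are intentionally left to configuration; all scores here
are per namespace. Graph-topology-only measures are out of scope.

## Prioritization

Candidates are scored against a non-empty training set on five
channels: adjacency count in the interaction graph, count of training
genes sharing ≥ 1 complex, count sharing ≥ 1 pathway, best Jaccard
overlap of propagated term sets, and best Lin/BMA functional similarity.
Jaccard on propagated sets is our choice of overlap statistic; the
channel family follows the common evidence types of rank-aggregation
prioritizers. Aggregation is deliberately simple and documented as
inspired-by rather than identical-to any published tool: per channel,
rank available candidates descending with average-rank ties, normalize
by the number ranked, impute 0.5 for candidates where the channel is
undefined, average over enabled channels, and order ascending with a
lexicographic gene-id tie-break so the output is deterministic. Training
genes are excluded from the ranking (the benchmark protocol hides the
disease gene from training). Count channels are considered available
whenever their data source is present; the two annotation channels are
per-candidate unavailable without usable terms.

The evaluator reports response rate (fraction of cases yielding a
ranking), TPR@k% (fraction of responding cases whose disease gene has
rank ratio = 100·rank/candidates ≤ k) and the median rank ratio, with
TPRs and the median over responding cases.

## Synthetic data

Generators are pure functions of a `FixtureSpec`; each draws from a
stream keyed by (seed, generator name), so adding a generator never
perturbs another's output, and per-case benchmark streams are keyed by
case index so changing the case count leaves earlier cases intact.

- **Ontology**: one namespace, term 0 the root, each later term takes
  1–2 parents among earlier terms — acyclic by construction. Default 50
  terms.
- **Corpus**: each of 200 genes draws max(1, Poisson(3)) distinct
  non-root terms uniformly.
- **Networks**: Bernoulli edges at density 0.05, complexes of 3–8 and
  pathways of 5–15 random genes.
- **Genome fixture**: 26 non-overlapping haplotype blocks on one
  chromosome, 1–3 genes per block, one tag SNP per block given in
  old-assembly coordinates; mapping multiplicities drawn from {1, 2, 3}
  with the exact expected pipeline row count recorded as ground truth;
  two registry releases differing in the pinned version of the final
  mapping, with the changed keys recorded.
- **Benchmark**: per case, 5 training genes share a 6-term annotation
  pool and complex/pathway/edge affinity; each of 50 candidates is
  linked to each unit of training evidence independently with
  probability θ (planted gene) or 0.1 (background). θ = 0.1 reduces
  exactly to the exchangeable null, under which the planted gene's rank
  ratio is uniform (mean 51 % for 50 candidates). θ defaults to 0.8.

The generated data is structurally faithful (file formats, DAG-ness,
multiplicities, closed intervals) but statistically naive: GO term
depth/breadth distributions, interactome degree heterogeneity and human
LD structure are not modelled. Passing tests therefore demonstrate the
correctness of the machinery — counts, expansions, exact statistics,
rank laws — not field performance on real databases, which depends on
the annotation density and bias of the actual sources.

## Problem sizes and numerics

Test and acceptance runs use deliberately modest sizes: exhaustive
hypergeometric enumeration for all populations N ≤ 12 (every admissible
(N, K, n, k) — 1 819 tuples × 3 modes), 10 000 random LD count tables,
1 000 enrichment null replicates, and 200 benchmark cases per condition;
these sizes give stable statistics while keeping a full run in seconds
to a few minutes. Float comparisons against exact-rational oracles use
1e−12 absolute tolerance; BH and rank computations are vectorized
through numpy/scipy (`rankdata` with average ties). Degenerate inputs —
empty tables, header-only files, monomorphic loci, unannotated objects,
empty study sets after corpus intersection — all have defined, typed
behaviour exercised in the unit suite.
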