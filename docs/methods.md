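# Methods

## Model and procedure

`motifsig` treats enhancer recognition as supervised binary
classification of DNA sequences and searches for the smallest
combination of short-motif frequency features that maximizes held-out
classification performance.

**Encoding.** A sequence of length *L* over {A,C,G,T,N} maps to 346
features: the 4 mononucleotide frequencies, the 6 aggregate two-base
frequencies (each the sum of two mononucleotide frequencies, one per
unordered base pair), and all 16 + 64 + 256 di/tri/tetranucleotide
frequencies in lexicographic order. Every count is divided by *L*
itself, not by the number of k-mer windows *L−k+1*; this makes values
directly comparable across sequences of different lengths at the cost
of a ≤ 3/L downward bias for longer k-mers (`denominator="windows"`
switches to the window count). Windows containing N contribute to no
count and the denominator is not adjusted. k-mers are *not* merged with
their reverse complements — the catalog size 256 for tetranucleotides
requires strand-specific counting — and sequences are ingested from the
+ strand only, since bidirectionally transcribed enhancers have no
natural orientation.

**Negative controls.** Without an experimental gold-standard negative
set, two constructions are provided. (1) *Random controls*: each
positive is copied and every non-N base is independently substituted
with probability `substitution_rate` (default 0.1; substituted bases
uniform over the three alternatives). Any candidate identical to a
sequence in the known-positive universe is regenerated (default up to
20 attempts). The default rate 0.1 was chosen once: it preserves
realistic base composition (~90% identity) while disrupting most
k-mer-level signal; it is exposed in `MutationConfig` and surfaced in
run manifests. Whether the original protocol mutated a fixed or a
variable number of positions per sequence is not specified anywhere we
could rely on; per-base Bernoulli substitution is our concretization,
which makes the Hamming distance Binomial(L, rate). (2) *One-vs-all*:
for a target facet (cell type/tissue), positives are its exclusively
transcribed enhancers (ids appearing in no other facet) and negatives
are the union of all other facets' exclusive enhancers; facets with
fewer than 5 exclusive enhancers are rejected as too small to train on.

**Gini ranking (phase 1).** Each feature column is discretized into at
most `n_bins` = 10 equal-frequency bins (duplicate quantile edges
merged); the score is the reduction in Gini impurity of the class
variable, Gini(Y) − Σ_b (n_b/n)·Gini(Y|bin b). Equal-frequency binning
with 10 bins is our concretization of a discretization-based Gini
filter; the bin count is configurable. For binary labels scores lie in
[0, Gini(Y)] ⊆ [0, 0.5]; constant features score 0. Ties are broken by
catalog order, making the ranking fully deterministic. The ranking API
is a plain (order, scores) pair so alternative filters (mRMR, Fisher
score) could be slotted in; they are not implemented.

**Selection (phase 2).** Filter rankings treat features independently,
which can be suboptimal for classification. The greedy mitigation is to
evaluate only the 346 nested top-K prefixes, never all subsets. Each
prefix is evaluated by an unregularized logistic regression under
repeated stratified random splits — 20% training / 80% testing, 300
runs by default (the small training share deliberately favors
generalization) — and characterized by the *mean* MCC across runs; the
selected signature is the prefix with maximal mean MCC, ties toward
smaller K. Fresh independent splits are drawn per run and per candidate
prefix, each seeded from a deterministic per-K stream, so reruns with
the same seed reproduce results exactly.

**Logistic fit.** The unregularized binomial maximum-likelihood fit is
computed by Newton/IRLS with step-halving (likelihood never decreases).
Convergence is declared when the score equation residual falls below
`tol·n` (`tol` = 1e-8, cap 200 iterations). On (quasi-)separated data
the likelihood has no finite maximizer; the fit at the cap is returned
with `converged=False` — its probabilities saturate, which is exactly
what thresholded classification and ranking metrics need. An
all-constant design is an error. Class prediction thresholds the
predicted probability at 0.5 (a configuration choice; no other
convention is documented for the original).

**Metrics.** Confusion-count metrics at the 0.5 threshold:
sensitivity, specificity, PPV, GM = √(sens·spec), MCC (0 when the
denominator vanishes; PPV reported as 0 with a flag when no positive
predictions exist). AUROC uses the tie-aware mid-rank trapezoidal
estimator and AUPRC the step-wise precision–recall sum (both via
scikit-learn; tests verify them against brute-force pairwise and
threshold-sweep recomputations).

**Benchmarking.** KNN (Euclidean distance on raw frequencies;
optional z-scoring off by default) and bagged decision trees are tuned
over the default grids K ∈ {3,4,5,6,7,8,20} and B ∈
{20,30,40,50,60,70,150} by mean GM on a tuning pass, then evaluated
over the full protocol (60% train, 100 runs). The tuning pass uses the
same split protocol with a seed stream disjoint from the final
evaluation; the original tuning split is not documented, so this is a
design choice of this package. The Vargha–Delaney A statistic,
A = (#{x>y} + ½#{x=y}) / (|x||y|), quantifies how often one method's
per-run metric exceeds another's (0.5 = stochastic equality).

## Synthetic data generator

The generator emulates facet-structured enhancer data: positives are
i.i.d. draws from a background nucleotide model (default uniform) of
length 300 — a round enhancer-scale size — with planted k-mers
inserted; negatives are background draws or mutated positives. For a
planted k-mer with enrichment multiplier *e*, the inserted copy count
per sequence is Poisson((e−1)·E_bg) with E_bg = (L−k+1)·P_bg(kmer), and
copies overwrite the background at uniform non-overlapping positions,
so total occurrences have expectation ≈ e·E_bg and *e* = 1 plants
nothing (an exact null). Per-facet private motifs model cell-type
specificity; a motif planted in all facets should attain cross-facet
selection frequency 1.0 and private motifs 1/n_facets, which the tests
verify.

What the generator does **not** emulate: positional structure
(enhancers are not i.i.d.; CpG and TA dinucleotide skews, repeats and
GC isochores are absent), correlated motif co-occurrence, expression
heterogeneity across cells, and any chromatin context. Passing tests
therefore demonstrate that the pipeline recovers planted
frequency-level signal under controlled conditions — not that any
particular motif is biologically predictive in real enhancer catalogs.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline at 300 positives
+ 300 negatives of 300 bp with three 5×-enriched planted
tetranucleotides, 50-run split protocols and prefix grids up to K = 30;
these sizes give stable recovery statistics while keeping a complete
run to minutes on one CPU. Equal-frequency binning merges duplicate
quantile edges, so low-cardinality columns degrade gracefully to fewer
bins. Runs in which a random split loses a class, or the restricted
design is constant, are skipped with a warning; more than 10% skipped
runs aborts the evaluation. Summaries use the sample standard deviation
(ddof = 1).

## Known limitations

- Only ranked prefixes are evaluated; a signature that requires
  skipping a highly ranked but redundant feature cannot be found.
- The Gini filter scores features marginally; strongly correlated
  k-mers (a planted tetramer and its constituent trimers) enter the
  ranking together, which can pad the selected prefix.
- Mutation-based negatives inherit the positives' base composition
  only approximately (substitutions are uniform over alternatives, so
  composition drifts toward uniform at high rates).
- BED ingestion extracts + strand sequence only and applies no
  repeat-masking; sequences are used as given.
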