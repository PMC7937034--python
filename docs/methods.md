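# Methods

This note documents the models implemented in `funlink`, the defaults and
why they were chosen, what the synthetic benchmark generator does and does
not emulate, and the numerical conventions used throughout.

## Functional association inference

**Gold standard.** Experimentally reported protein interactions carry a
study count and a throughput flag. An interaction is kept as a positive
training example iff it was reported by at least two independent studies
*or* by at least one low-throughput experiment; interactions seen only
once and only in high-throughput screens are removed (high-throughput
single reports have the highest false-positive rates). The filter is
fail-closed and order-preserving.

**Negative sampling.** Negatives are unordered gene pairs drawn uniformly
from the universe, excluding self-pairs and all positives, at a 1:100
positive-to-negative ratio. The premise is sparsity: in a genome-scale
interactome roughly one pair in a thousand interacts, so random pairs are
almost always true negatives and the residual label noise is small.
Sampling is exact (exactly `ratio × |positives|` distinct pairs) and
reproducible per seed; an infeasible request raises instead of silently
shrinking.

**Features.** Six evidence categories produce 36 named features (census
1 interolog / 3 phylogenetic profile / 23 domain interaction /
4 colocalization / 2 coexpression / 3 shared annotation). The exact
functional forms are this package's documented choices — the pipeline
contract is the category census, symmetry, finiteness and the AUC gate,
not any single formula. Representative forms: Pearson/Spearman
correlation for coexpression; Pearson, Jaccard and mutual information
(bits) for binary phylogenetic profiles; Jaccard/overlap/indicator for
compartments; shared-term count, Jaccard and minimum information content
(`IC = −log2` of term frequency among annotated genes — any monotone base
is AUC-invariant) for annotations; and a parameterised 4 aggregations ×
5 normalisations family plus three set-overlap features for interacting
domain pairs. Missing evidence for a gene scores 0 ("no evidence of
association"), never NaN: margin classifiers need complete vectors, and
zero biases toward the no-association prior. A once-per-gene warning is
logged.

**Feature selection.** Each feature's ROC AUC against the gold labels is
computed with the tie-aware Mann–Whitney statistic
(`P(s⁺ > s⁻) + ½P(tie)`); features with AUC *strictly* greater than 0.6
are retained.

**SVM.** A soft-margin RBF SVM (kernel `exp(−‖x−y‖²/2σ²)`, i.e.
scikit-learn `gamma = 1/(2σ²)`), with features standardised inside the
model pipeline. σ and C are grid-searched (defaults log-spaced:
σ ∈ 2⁻⁴…2⁴, C ∈ 2⁻²…2⁶; the pipeline front-end defaults to a coarser
3 × 3 grid to stay interactive) by stratified k-fold cross-validation
(k = 5) maximising the harmonic mean of sensitivity and specificity,
macro-averaged over folds — macro averaging is stable at 1:100 imbalance,
and stratification guarantees positives in every fold. Grids are sorted
internally, so the selected (σ, C) is independent of the order the caller
lists them; ties break toward the smaller (σ, C). Both the CV-mean and
the refit-apparent sensitivity/specificity are reported and labelled,
since they answer different questions (generalisation vs. description);
size estimation uses the conservative (minimum) sensitivity.

**Confidence.** A pair is called positive when its signed decision value
is > 0; the reported confidence is |value| clipped at 1, so calls beyond
the unit margin score exactly 1 and calls inside the margin score
proportionally lower. No probability calibration is applied — the margin
is the native geometry of the classifier.

Because the gold standard consists of protein interactions while the
model scores *all* gene pairs, training transfers interaction-strength
knowledge to the broader notion of strong functional association; no
extra mechanism is needed beyond train-on-gold, score-everything.

## Interactome size estimation

A predictor with known sensitivity and specificity applied to all
`N_all` gene pairs is expected to emit
`N_int·sens + (N_all − N_int)(1 − spec)` positives. Equating to the
observed prediction count and solving gives
`N_int = (N_pred − (1 − spec)·N_all) / (sens − (1 − spec))`. The equation
is well-posed only when sensitivity exceeds the false-positive rate;
violations raise, and a negative solution is reported as an infeasibility
diagnosis, never clamped. `N_all` is always an explicit, logged input
(`n(n−1)/2` from a stated gene universe) because it dominates the
solution and should never be defaulted silently. Derived quantities:
expected covered interactions (`sens × N_int`), expected precision
(covered / predictions), and pairs-per-interaction (`N_all / N_int`).
At genome scale (88 069 predictions, conservative sensitivity 0.3248,
specificity 0.9998, a 19 711-gene universe) this yields ≈ 1.52 × 10⁵
interactions — about one per 1 280 pairs — with ≈ 49 000 true
interactions among the predictions (≈ 56% expected precision). Percent
roundings follow display convention: one decimal for overlap
percentages, two for support rates (half-up).

## Gene set linkage analysis

**Q1 (density).** The inter-set density is the number of interactome
edges with one endpoint in each set divided by the number of *distinct
unordered cross pairs*, `|A||B| − k − k(k−1)/2` with `k = |A∩B|`; the
subtraction handles overlapping sets (self-pairs and double-counted
intersection pairs are removed; an edge inside the intersection counts
once). The default threshold, density > 0.01, is a fixed criterion, not
a second resampling test. Degenerate set pairs with zero cross pairs
raise.

**Q2 (permutation null).** The null model is the observed interactome
randomised by double-edge swaps: repeatedly pick two edges (a,b), (c,d)
and replace them with (a,c), (b,d) unless that creates a self-loop or a
duplicate edge. Every gene keeps its exact neighbour count, so hub-rich
set compositions generate exactly as many expected cross edges under the
null as in the data, and only the specific wiring can produce an excess.
`swaps_per_edge × n_edges` attempts are made per null network
(default 10 per edge, a standard mixing heuristic; rejected proposals
are skipped). Each reference set gets its own independent null stream.
The p-value is the add-one estimator
`p = (1 + #{d_null ≥ d_obs}) / (1 + n_perm)`: never zero, and exact tie
handling is guaranteed by comparing integer edge counts rather than
floating densities. The default `n_perm = 1999` makes the default
criterion `p < 0.001` attainable (minimum p = 1/2000); a configuration
whose α is below `1/(n_perm+1)` warns that Q2 can never pass. Q2 is
evaluated only for Q1-passing sets — the criteria are conjunctive, so
skipping Q2 on Q1 failures cannot change the reported set (skipped sets
carry p = 1 and a "not tested" flag).

Note on discreteness: with a strict `p < α` rule the largest attainable
rejection rate is `⌊α(m+1) − 1⌋/(m+1)` (e.g. 9/200 = 0.045 at α = 0.05,
m = 199). Calibration checks therefore compare observed type-I rates to
this exact discrete level, not to the nominal α.

No multiple-testing correction is applied across reference sets — raw
p-values are exposed so users can apply their own. ID mapping to the
canonical namespace is order-preserving, collapses post-mapping
duplicates, reports (never drops) unmapped tokens, and fails when
nothing maps. The TSV report opens with exactly ten `#` parameter lines
followed by one row per reference set, including the connecting
query-reference gene pairs.

## Guilt-by-association benchmark

For each gene, candidate terms are those annotated (in the "old",
construction-time layer) to at least one first-degree neighbour, scored
by the one-sided hypergeometric over-representation p-value against the
annotated-gene universe (genes bearing ≥ 1 annotation — not all network
genes, which would inflate enrichment on sparsely annotated fixtures).
The gene itself never contributes to its own neighbour counts. No
multiple-testing correction is applied: the cutoff axis of the
precision-recall sweep plays that role. Recall counts recovered *new*
(held-out) gene-term annotations; precision counts predictions
consistent with *any* known annotation, old or new — deliberately
reproducing the standard evaluation's acknowledged optimism when shared
annotation also fed the network (the report output documents this).
Cutoffs with zero predictions are skipped with a log note; AUC is the
trapezoid over recall-sorted points (0 when fewer than two points
survive).

## Synthetic benchmark generator

The generator plants functional modules and threads the same module
signal through every evidence category:

* **Truth interactome:** Bernoulli edges, dense within modules
  (default 0.5), near-absent between (default 10⁻⁴). The default bundle
  (1000 genes, 200 modules of 4–6) has ≈ 1 050 edges over ≈ 5 × 10⁵
  pairs — roughly one edge per 475 pairs, the sparse regime that the
  1:100 negative-sampling protocol presumes. (An earlier dense-module
  variant at ~8% edge density makes random negatives so contaminated
  that the 1:100 protocol collapses; sparsity is a modelling requirement,
  not a tuning knob.)
* **Expression:** Gaussian one-global-plus-one-module factor model giving
  exchangeable within-module Pearson correlation `rho_within` (0.7) and
  between-module `rho_between` (0.05).
* **Annotations / compartments / domains / phylogenetic profiles:**
  module-characteristic term, compartment and domain pools and a
  module presence pattern across 25 species, each corrupted at a 0.1
  per-item noise rate; interacting domain pairs are seeded within module
  domain pools (plus rare low-score cross-module pairs).
* **Interologs:** a second, independently drawn module-structured pair
  set (within-module probability 0.15 vs 5 × 10⁻⁴ between). They are
  deliberately *not* copied from the truth edges: evidence informs the
  labels only through module membership, so the no-structure null bundle
  is exactly uninformative (feature AUC → 0.5) instead of leaking labels.
* **Gold standard:** edges sampled from the truth with study counts in
  {1, 2, 3} and Bernoulli(0.5) throughput flags, covering both branches
  of the quality filter.
* **Corpus:** each gene-term link is assigned to the "new" layer with
  probability 0.3, emulating a later-annotations holdout without dates.

`null_bundle` equalises within/between rates (edges, correlation,
interologs); module-structured evidence then carries no information about
the Erdős–Rényi edges, which is the basis of the type-I-error and
AUC ≈ 0.5 property tests. Every bundle is a deterministic, byte-stable
function of its config, and all artefacts round-trip through the
package's own readers.

**What the generator does not emulate:** evidence resolution below module
level (two genes in one module are statistically identical, so a
classifier cannot separate within-module non-edges from edges — the
held-out ranking ceiling is set by interactome sparsity); realistic GO
DAG topology or annotation depth; inter-database ID noise; hub-heavy
degree distributions beyond what Bernoulli blocks produce; and genome
scale (19k+ genes). Passing tests therefore demonstrate correctness and
calibration of the machinery under controlled conditions, not real-data
performance.

## Problem sizes and numerical conventions

Desk-scale defaults used by the tests and the acceptance script: default
bundle 1000 genes / ~1 050 edges / 70 gold positives (≈ 5 900 labelled
pairs at 1:100); type-I calibration uses 100 structure-free 200-gene
networks × 20 random 50-gene reference sets at m = 199 permutations;
power uses 20 seeded two-module fixtures at m = 199; the
guilt-by-association comparison uses 240-gene six-module bundles. The
rewiring inner loop is numba-compiled (pure-Python fallback preserves
identical results) with a dense boolean adjacency matrix for O(1)
duplicate checks. All stochastic steps consume
`numpy.random.SeedSequence` streams spawned from a single seed; GSLA
results, fixtures and pipeline summaries are bit-reproducible for a
fixed seed. Edge scores round-trip text IO at six decimals. Duplicate
edges keep the maximum score (ties prefer experimental provenance) —
the conservative strongest-evidence rule. Self-pairs are rejected, not
dropped, to surface upstream ID-mapping bugs.

## Known limitations

* The 36 feature formulas are representative of their categories, not a
  reconstruction of any particular deployed system; the registry is
  pluggable for users who need different forms.
* The expected-precision derivation mixes an external sensitivity
  estimate with the predictor's own counts; its genome-scale value
  (≈ 56%) is reported from first principles and is sensitive to the
  assumed gene-universe size, which published summaries rarely state.
* Whole-interactome double-edge-swap nulls are approximate samplers of
  the uniform fixed-degree-sequence distribution; 10 swaps per edge
  mixes well at desk scale but very large or very constrained graphs may
  need more.
* The GBA precision metric is optimistic by construction (old
  annotations count as hits); only the *comparison* between networks on
  the same corpus is meaningful.
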