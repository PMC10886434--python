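# Methods

## Model

The pipeline factors a centered log-expression compendium X (genes ×
samples) as X ≈ M·A, where the columns of M are statistically independent
gene-weight signatures and the rows of A are their per-sample activities.
The working assumptions are the standard ones for ICA of transcriptomes:
regulatory signals are sparse in gene space (a component loads heavily on
a small member set, so its weight distribution is non-Gaussian), signals
combine approximately additively in log space, and the number of
meaningful components is far below min(genes, samples).

## Preprocessing

Expression enters as RPKM. We use log2(x + 1): base 2 makes weights and
activities read as fold changes, and pseudocount 1 keeps zeros at zero.
Centering subtracts, per gene, the **mean** log expression of the
reference-condition replicates (the reference may be a single sample, in
which case mean and sample coincide; with several replicates the mean is
the natural estimator). Activities are therefore expressed relative to
the reference condition.

QC computes all pairwise sample Pearson correlations and splits them into
replicate and non-replicate pairs. The pass rule is: replicate median
above non-replicate median **and** a one-sided Mann–Whitney test
(replicates stochastically larger) at α = 0.05. The rank test is what
makes the rule calibrated: under randomly shuffled replicate labels the
median of a small relabeled sample exceeds the remaining pairs' median
about half the time, while the rank test rejects at its nominal 5% rate.

## Robust ICA

A single FastICA run (scikit-learn: log-cosh contrast, parallel symmetric
fixed-point iteration, tolerance 1e-7, iteration cap 1000, whitening onto
exactly k principal components of the sample dimension) is not stable
across initializations, so the decomposition is repeated from
`n_restarts` seeds and only recurring components are kept:

1. Each restart decomposes a **bootstrap resample of the sample columns**.
   This is deliberate: the fixed points of the contrast function are
   properties of the data matrix, so on a *fixed* matrix even components
   fitted to noise recur across random initializations (we measured
   median cross-restart distances of 0.02 for pure-noise components).
   Requiring a component to survive data perturbation as well as
   re-initialization restores the intended null behavior: on i.i.d.
   Gaussian input the decomposition is empty.
2. Pooled sources (unit-norm, dominant weight made positive; A absorbs
   sign and scale) are clustered by DBSCAN on d = 1 − |Pearson r| with
   radius 0.2 and minimum cluster size ⌈n_restarts/2⌉; a cluster counts
   as robust when its members span at least half the restarts.
3. Each robust cluster contributes its **centrotype** — the member source
   minimizing the summed distance to the rest of the cluster.
4. A is recomputed as the least-squares projection of the *original* X
   onto the centrotype columns, so M·A is a well-defined reconstruction
   and explained variance (1 − ‖X − MA‖²_F/‖X‖²_F) is coherent and
   non-decreasing in the number of components.

Component identity is defined by content (matching by |correlation|),
never by column index. Note that FastICA removes each sample's mean
across genes, so a matrix with nonzero per-sample means retains that
offset as an unexplainable residual; reference-centered compendia are
close enough to column-centered for this to be a percent-level effect.

Dimensionality is chosen by sweeping candidate dimensions, classifying
each robust component as *single-gene* when one gene carries more than
0.7 of the column's squared norm, and selecting the smallest dimension
that maximizes the count of non-single-gene robust components. The 0.7
dominance fraction, the 0.2 clustering radius and the half-of-restarts
rule are exposed in the configuration.

## Member-gene extraction

For each M column, the D'Agostino–Pearson omnibus statistic
K² = Z²(skewness) + Z²(kurtosis) is computed on the current weights
(scipy's implementation of the standard transformations); while K²
exceeds the cutoff (default 550) the gene with the largest |weight| is
removed — ties broken by compendium order, earliest first — and the
statistic recomputed. Stripping stops at the cutoff or when 9 genes
remain (below that length the skewness/kurtosis standardizations are
unreliable and the statistic is reported as undefined, as it is for
zero-variance input). The removed genes are the members; the stored
threshold is the smallest removed |weight|, so membership is
|w| ≥ threshold at the boundary gene and strict above it. An initial K²
at or below the cutoff yields an empty iModulon, which is a legitimate
outcome (components fitted mostly to noise).

The K² cutoff's sensitivity depends on the length of the weight vector
and the shape of its tail: the kurtosis z-statistic saturates (roughly
√(9A/2) in the Anscombe–Glynn transform), so for ~1000-gene vectors a
purely symmetric two-sided tail can plateau *below* 550 while the same
tail on 3000 genes lands in the thousands. One-sided tails engage the
skewness arm, which does not saturate this way. This is one reason the
synthetic generator plants single-signed modules (below).

## Annotation

Member sets are tested against every regulon with the two-sided Fisher
exact test on the 2×2 partition of the gene universe (default universe:
all compendium genes, configurable). Benjamini–Hochberg q-values are
computed over the full iModulon × regulon family and called significant
at q < 1e-5. Recall = overlap/regulon size; precision = overlap/iModulon
size. When several regulons are enriched, the label joins them with '+'
if, among members covered by any enriched regulon, more than 0.6 lie in
the intersection of all of them (combinatorial regulation of the same
genes), else with '/'. The 0.6 intersection-dominance fraction
operationalizes what is otherwise a manual Venn-diagram call; the
underlying fractions are recorded so a curator can override.

iModulons without regulon hits can be annotated from motif evidence.
The package prepares the inputs for external motif tools: strand-aware
200-bp upstream windows that overlap no annotated gene (GFF3 + FASTA in;
0-based half-open internally; minus-strand windows reverse-complemented;
contig-edge-truncated windows dropped), optionally filtered by a
precomputed promoter-probability table at score > 0.8. A candidate TF is
validated when its expression correlates (two-sided Pearson p < 0.05)
with more than half of the iModulon's members; the TF-vs-activity
correlation is reported alongside.

## Activity analysis

Activities are summarized per condition (mean and sd; sd reported absent
for singleton conditions). Condition-responsive iModulons are ranked by
|mean activity difference| for a stated contrast with a z-like score
(difference over pooled within-condition sd); the top k (default 4) are
flagged active — a formalization of reading an activity heatmap.
TF–member networks keep edges with Pearson p < 0.05 and signed weights
(negative edges flag repressor candidates). Program trade-offs are
Pearson correlations between activity rows across all samples; aggregate
comparisons sum log expression over two gene sets per sample. Pearson
correlation and two-sided p-values are used throughout.

## Synthetic compendia

The generator emulates a ~100-sample × ~3000-gene single-species
compendium: disjoint sparse modules (default 5–20 genes), activities
drawn per replicate group from N(0, 1) and shared by the group's
replicates, i.i.d. Gaussian log-space noise (default sd 0.1), linear
expression 2^(8 + M·A + ε) so values resemble RPKM magnitudes, and a
sample-metadata table with a designated reference group. The reference
group's activities are subtracted from every group at generation time,
so the planted A is already relative to the reference and the
preprocessing chain recovers M·A up to noise exactly.

Member weights are ±weight_magnitude × (1 + U(0, 0.2)). By default all
members of a module share the positive sign: real iModulon member genes
are co-transcribed or co-regulated operons whose weights share a sign,
and a single-signed tail is what the K² skewness arm detects reliably at
any vector length (see above; with independent random signs, an evenly
balanced module's statistic can saturate below the 550 cutoff on
1000-gene vectors, which is a property of the statistic, not of the
inference). `weight_sign="random"` restores independent signs.
The default weight magnitude is 1.0 log2 units — about a two-fold
expression swing per unit activity, typical of regulated bacterial
operons. One member gene per module is designated its TF (weight forced
positive), so TF expression tracks module activity with r = 1 at zero
noise. Optional per-module, per-group activity shifts create
condition-responsive or dose-response designs.

Regulons are derived from the planted modules by replacing
⌈jitter × size⌉ members with random non-member genes (size-preserving;
jitter 0 gives exact regulons, jitter 1 disjoint ones), emulating the
partial overlap between data-driven modules and curated databases.

What the generator does **not** emulate: read-count sampling noise and
library-size effects, batch effects between source studies, gene-length
biases, heteroskedastic per-gene variance, or operon structure on a
genome. Passing tests therefore demonstrate correctness of the inference
machinery on compendia satisfying the model's assumptions, not
robustness to every artifact of real RNA-seq. The noise model for
RPKM-scale data is a modeling choice (additive Gaussian in log space).

## Problem sizes and determinism

The test suite and the acceptance script use planted compendia of 1000
genes × 50 samples with 5 modules (20 ICA restarts, 10 generator seeds)
and smaller fixtures of 300 × 20 for unit tests — sizes at which every
stage's behavior is already asymptotic while the whole suite runs in
about a minute. All randomness flows through explicit integer seeds
(NumPy `default_rng` / scikit-learn `random_state`); reruns with the
same configuration reproduce all outputs bitwise, and the pipeline
manifest records seeds and parameters for replay.

## Known limitations

- OptICA's selection rule is one admissible reading of the
  robust/single-gene counting idea; the dominance fraction and cluster
  radius defaults are conventions, exposed in config.
- The boundary behavior of K² stripping (stop at ≤ cutoff; 9-gene floor;
  threshold stored as smallest removed |weight|) involves choices the
  statistic itself does not dictate; they are documented above.
- Fisher tests treat the gene universe as exchangeable; universe choice
  (all genes vs annotated genes) shifts p-values and is configurable.
- The '+'/'/' labeling and the "active iModulon" flag are formalizations
  of judgments that practitioners often make by eye; both record the
  underlying numbers for manual review.
- Motif discovery, motif comparison and promoter prediction are external
  tools; the package only prepares their inputs and consumes their
  score tables.
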