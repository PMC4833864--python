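# Methods

## Model and procedure

The package assumes two feature-by-sample matrices profiling exactly the
same samples (the matched-column contract): a main matrix *M*
(*n₁* × *n*) to be adjusted and an associated matrix *C* (*n₂* × *n*)
supplying independent evidence about the same sample structure. The
working premise is that pairwise sample distances measured on the two
platforms should agree, and that disagreement is dominated by technical
noise and platform-specific bias rather than biology. Adjustment is
strictly row-wise and consists of three stages.

**1. Feature correspondence.** If the two feature ID sets are identical,
rows correspond one-to-one and *C* is simply reordered to *M*'s feature
order. Otherwise genomic annotations drive a neighbor search: each main
feature is anchored at a single coordinate (strand-aware TSS for genes —
interval start on `+`/unknown strand, end on `-`; integer midpoint
`floor((start+end)/2)` for interval features), and the associated features
on the same chromosome within `max_distance` of that anchor, sorted by
distance and truncated to `max_neighbors`, form its neighbor set.
Distance ties are broken by lower coordinate, then lexicographic feature
ID, so the map is byte-identical regardless of input record order.
Coordinates are interpreted as BED-style 0-based half-open; annotations
with duplicate feature IDs are rejected outright because silent
disambiguation risks matching the wrong locus. A main feature with no
neighbor (or missing from the annotation) is flagged and passes through
adjustment untouched.

**2. Summarization.** Each non-empty neighbor sub-matrix is reduced to a
single row: every neighbor row is standardized, the k × k Pearson
correlation matrix is eigendecomposed, and the summary is the score
vector of the leading eigenvector (the eigenvector-weighted sum of the
standardized rows). If the summary anti-correlates with the main row it
is negated, so the gating correlation below is always ≥ 0 on this path.
The summarized matrix *C′* has exactly *M*'s shape and feature order.

**3. Correlation-gated update.** With ρ = cor(*cᵢ*, *mᵢ*) (Pearson) and
cutoffs `cutoff1 < cutoff2`:

* ρ ≤ cutoff1 → keep the row (scenario 1);
* cutoff1 < ρ ≤ cutoff2 → `scale(m) + ρ·scale(c)` (scenario 2);
* ρ > cutoff2 → leading-PC score of the 2 × 2 correlation matrix of
  {*m*, *c*}, which is proportional to `scale(m) + scale(c)`, negated if
  anti-correlated with *m* (scenario 3).

The result is rescaled to the original row's mean and s.d., making
self-adjustment an exact fixed point and conserving per-row moments to
floating precision.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `cutoff1` | 0 | below/at: no adjustment; only positive concordance is treated as meaningful |
| `cutoff2` | 0.5 | above: full PC replacement; between: weighted sum |
| `cutoff2_mode` | `fixed` | `empirical-third` replaces cutoff2 with the (1 − 1/3) quantile of the non-skipped row correlations |
| `max_neighbors` | 50 (peaks around genes), 20 (genes around peaks) | neighbor count cap |
| `max_distance` | 100 000 bp | anchor-to-anchor window, both directions |
| anchor rules | TSS for genes, midpoint for intervals | configurable per matrix |

The empirical cutoff uses a linear-interpolation quantile so "roughly one
third in scenario 3" is reproducible; it is computed on the final
sign-aligned summarized rows, since those are the quantities actually
gated. If the selected value fell at or below `cutoff1` (possible only
for pathological correlation distributions) it is clamped to
`cutoff1 + 1e-12` with a warning, preserving the cutoff ordering
invariant.

## Numerical choices

* **Standardization**: centring to mean 0 *and* scaling to s.d. 1, with
  the sample (n−1) denominator throughout. Centring and denominator
  choices only affect intermediate vectors up to affine maps that the
  final rescaling absorbs.
* **Degenerate rows**: a row counts as constant when its variance is at
  most 1e−12 times max(mean square, 1); such rows (or rows whose partner
  is constant) are passed through unchanged, labelled `skipped`, and
  logged with their feature IDs.
* **Eigen-tie-breaking**: among eigenvectors whose eigenvalues are within
  relative 1e−9 of the maximum, the score vector with the largest
  absolute correlation with the reference row wins; exact ties fall to
  the lowest eigenvector index. Eigenvectors are unit-normalized; only
  the direction matters because of the final rescaling.
* **Gate boundaries**: the scenario-1 gate is a literal `≤ cutoff1`, so a
  row with ρ exactly 0 under the defaults is left unchanged. On the
  summarized path sign alignment makes ρ ≥ 0, so scenario 1 is then
  reachable only at this measure-zero boundary.

## Evaluation metrics

**Clustering recovery.** K-means is run repeatedly on the sample columns
(samples as points in the full feature space, raw unscaled values):
single-init Lloyd's algorithm with k initial centres drawn uniformly from
the data points, one derived child seed per repetition from a master
seed. Each run is scored against ground-truth labels with the adjusted
Rand index in the Hubert–Arabie chance-corrected pair-counting form,
implemented from the contingency table; a degenerate denominator (both
partitions trivial) returns 1 for identical partitions, else 0, with a
logged note. Because each repetition uses a single random initialization,
some runs land in local optima even on cleanly separated clusters — the
distribution over repetitions, not any single run, is the object of
interest.

**Concordance deltas.** Per feature, the change in Spearman correlation
(average ranks on ties) between the main row and a held-out partner row,
after minus before adjustment; summarized by the fraction of features
with a strictly positive delta and a one-tailed paired t-test
(alternative: correlations increased).

## Synthetic data

`generate_paired_dataset` emulates the structure the method targets:
samples carry balanced cluster labels (round-robin, then shuffled); each
main feature has a latent signal with one Gaussian per-cluster mean
(`signal_sd`, default 1.0) shared with its assigned associated partners;
both platforms add independent Gaussian noise (`noise_sd`, default 0.5);
and a scalar Gaussian offset (`bias_sd`, default 2.0) is added to each of
`n_biased_samples` (default 10 of 60) main-matrix columns, shared by all
features in the column — a batch-like column effect that makes those
samples outliers in sample space, which is exactly the distortion the
adjustment can remove. Defaults are 300 main features with 5 partner
peaks each, 4 clusters. Genomic coordinates place each latent unit in
its own window, windows tiled every 10 × `max_distance`, so neighbor
search recovers the true partnership exactly and never leaks across
units. Independent random streams (split from one seed) drive labels,
signal, each platform's noise and the bias, so switching the bias off
reproduces every unbiased column bit for bit.

`generate_concordance_triple` builds the matched one-to-one setting
(expression adjusted by a second expression platform, scored against
held-out copy number): three matrices sharing the latent signal with
independent noise, the main one additionally biased.

What the generator deliberately omits: count-like distributions and
heteroscedasticity, correlated noise across features, partial overlap
between platforms' signals, distal (beyond-window) regulatory structure,
and unbalanced or hierarchical cluster layouts. Passing tests therefore
show the method removes additive column bias under shared Gaussian
cluster signal; they do not certify behaviour on raw counts or on biases
correlated with biology.

## Problem sizes

The test and reproduction runs use 60 samples × 300 main features × 1500
associated features, 100 K-means repetitions and 10 dataset seeds —
small enough to iterate on comfortably while leaving all rates and
comparisons stable across seeds.

## Known limitations

* One associated matrix at a time; integrating several sources requires
  repeated runs.
* Row-wise updates cannot correct biases that reorder features within a
  sample without changing sample-space geometry.
* Scenario 2's weighting (`scale(m) + ρ·scale(c)`) is the minimal
  correlation-weighted sum; the `adjust_row` surface accepts alternative
  cutoffs but not alternative weight functions.
* Dense TSV only; matrices must fit in memory.
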