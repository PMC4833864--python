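# mancie

Bias correction and integration of paired high-dimensional genomic data
matrices.

Many genomics studies profile the same samples on two platforms — gene
expression and copy number on a tumour cohort, DNase-seq accessibility and
exon arrays on a cell-line panel. Each platform carries its own technical
noise, and one often carries a batch-like bias confined to a subset of
samples. `mancie` adjusts a **main** feature-by-sample matrix *M* row by
row using the concordant information in a column-matched **associated**
matrix *C*, keeping the biological sample structure the two platforms agree
on and damping what they do not. It is aimed at computational biologists
integrating two dense omics matrices over the same samples before
clustering, survival modelling or concordance analyses.

## Method

For each main row *mᵢ* and its associated row *cᵢ* (one-to-one matched, or
summarized from nearby features, see below), let ρ = cor(*cᵢ*, *mᵢ*) be the
Pearson correlation and `scale(x)` standardize a row to mean 0, s.d. 1
(sample s.d., *n*−1). With cutoffs `cutoff1 < cutoff2` (defaults 0 and
0.5):

1. **ρ ≤ cutoff1** — keep *mᵢ* unchanged (no usable concordance);
2. **cutoff1 < ρ ≤ cutoff2** — correlation-weighted sum
   `scale(mᵢ) + ρ·scale(cᵢ)`;
3. **ρ > cutoff2** — the first principal component of the 2 × 2 Pearson
   correlation matrix of {*mᵢ*, *cᵢ*}, i.e. the score vector
   ∝ `scale(mᵢ) + scale(cᵢ)`, negated if it anti-correlates with *mᵢ*.

The updated row is then rescaled to the mean and s.d. of the original
*mᵢ*, so per-row moments are conserved exactly and only the pattern across
samples changes. `cutoff2` can also be chosen empirically as the
correlation quantile that sends roughly one third of the rows through
scenario 3 (`--auto-cutoff2`).

When the two matrices measure different feature spaces (genes vs. peaks),
each main feature is paired with the associated features whose genomic
anchors (strand-aware TSS for genes, interval midpoint for peaks; BED
coordinates) lie within a window — by default up to 50 peaks within 100 kb
of a gene, or up to 20 genes around a peak — and the neighbor sub-matrix is
reduced to the score vector of its leading correlation-matrix PC,
sign-aligned with the main row.

The package also ships the evaluation metrics used to judge the
adjustment (repeated randomly-initialized K-means scored with the adjusted
Rand index against known labels; per-feature Spearman concordance deltas
with a one-tailed paired t-test) and a synthetic generator of paired
matrices with shared cluster signal, independent platform noise and a
column bias on a sample subset.

## Worked example

```python
import mancie as mc

# 60 samples in 4 clusters; 300 genes x 1500 peaks sharing a latent
# signal; an additive column bias (sd 2.0) on 10 samples of the main matrix
ds = mc.generate_paired_dataset(seed=1)

result, report = mc.adjust_pair(
    ds.main, ds.assoc, ds.main_annot, ds.assoc_annot,
    cutoff2_mode="empirical-third",
)
print(report.scenario_counts, round(report.cutoff2, 3))

raw = mc.kmeans_ari_distribution(ds.main, ds.true_labels, k=4, n_reps=100, seed=1)
adj = mc.kmeans_ari_distribution(result.adjusted, ds.true_labels, k=4, n_reps=100, seed=1)
print(round(raw.mean_ari, 3), "->", round(adj.mean_ari, 3))
```

prints

```
{'skipped': 0, 'scenario1': 0, 'scenario2': 200, 'scenario3': 100} 0.67
0.699 -> 0.785
```

The empirical cutoff (0.67) routes exactly one third of the 300 genes
through the principal-component update; the mean adjusted Rand index of
repeated K-means against the true sample clusters rises from 0.699 to
0.785 after adjustment — the biased columns stop acting as outliers.

The same steps are available from a shell:

```sh
mancie simulate --seed 1 --outdir data/
mancie adjust --main data/main.tsv --assoc data/assoc.tsv \
    --main-annot data/main_annot.bed --assoc-annot data/assoc_annot.bed \
    --anchor-main tss --auto-cutoff2 --out adjusted.tsv --diagnostics-out diag.tsv
mancie evaluate --data adjusted.tsv --labels data/labels.tsv --k 4 --out metrics.tsv
```

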