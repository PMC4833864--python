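"""Desk-scale evaluation metrics.

Two families of checks quantify whether adjustment helped:

* sample-clustering recovery — repeated K-means on the sample columns,
  scored against ground-truth labels with the adjusted Rand index (ARI,
  Hubert–Arabie chance-corrected pair-counting agreement);
* per-feature cross-matrix concordance — the change in Spearman
  correlation between each feature's row and its partner row (e.g. copy
  number vs. expression of the same gene) before vs. after adjustment,
  with the fraction of improved features and a one-tailed paired t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import comb
from sklearn.cluster import KMeans

from .core import OmicsMatrix

logger = logging.getLogger("mancie")


@dataclass
class ClusteringEvaluation:
    ari_values: np.ndarray
    n_reps: int
    k: int
    seed: int

    @property
    def mean_ari(self) -> float:
        return float(np.mean(self.ari_values))


@dataclass
class ConcordanceResult:
    """Per-feature Spearman deltas plus summary statistics."""

    deltas: np.ndarray
    fraction_positive: float
    t_statistic: float
    p_value: float


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert–Arabie adjusted Rand index of two partitions.

    ARI = (Index - E[Index]) / (Max - E[Index]) over the pair-counting
    contingency table; 1 for identical partitions, ~0 for chance-level
    agreement.  When the denominator degenerates (both partitions trivial)
    the convention here is 1 for identical partitions, else 0.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)
    sum_cells = comb(contingency, 2).sum()
    sum_rows = comb(contingency.sum(axis=1), 2).sum()
    sum_cols = comb(contingency.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_rows * sum_cols / total
    max_index = 0.5 * (sum_rows + sum_cols)
    denom = max_index - expected
    if abs(denom) < 1e-12:
        same = np.array_equal(ai, bi)
        logger.info("degenerate ARI denominator; returning %d by convention", int(same))
        return 1.0 if same else 0.0
    return float((sum_cells - expected) / denom)


def kmeans_ari_distribution(
    data: OmicsMatrix,
    true_labels,
    k: int,
    n_reps: int = 100,
    seed: int = 0,
) -> ClusteringEvaluation:
    """ARI distribution over repeated randomly-initialized K-means runs.

    Samples are the points (columns), features the dimensions.  Each
    repetition is Lloyd's algorithm from k initial centres drawn uniformly
    from the data points, on raw (unscaled) columns; the master seed
    derives one child seed per repetition, so the whole distribution is
    reproducible.
    """
    true_labels = np.asarray(true_labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > data.n_samples:
        raise ValueError(f"k={k} exceeds the {data.n_samples} samples")
    if true_labels.size != data.n_samples:
        raise ValueError("true_labels length must equal the sample count")
    X = data.values.T  # samples as points
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    aris = np.empty(n_reps)
    for r in range(n_reps):
        km = KMeans(
            n_clusters=k,
            init="random",
            n_init=1,
            algorithm="lloyd",
            random_state=int(child_seeds[r]),
        ).fit(X)
        aris[r] = adjusted_rand_index(km.labels_, true_labels)
    return ClusteringEvaluation(aris, n_reps, k, seed)


def concordance_delta(
    before: OmicsMatrix, after: OmicsMatrix, partner: OmicsMatrix
) -> ConcordanceResult:
    """Per-feature change in Spearman correlation with a partner matrix.

    For each feature, ``delta = spearman(after_row, partner_row) -
    spearman(before_row, partner_row)`` (average ranks on ties).  Reports
    the per-feature deltas, the fraction strictly positive, and the
    one-tailed paired t-test (alternative: after > before).
    """
    for other, name in ((after, "after"), (partner, "partner")):
        if other.values.shape != before.values.shape:
            raise ValueError(f"{name} matrix shape differs from before")
        if other.feature_ids != before.feature_ids:
            raise ValueError(f"{name} matrix feature order differs from before")
        if other.sample_ids != before.sample_ids:
            raise ValueError(f"{name} matrix sample order differs from before")
    n = before.n_features
    r_before = np.empty(n)
    r_after = np.empty(n)
    for i in range(n):
        r_before[i] = stats.spearmanr(before.values[i], partner.values[i]).statistic
        r_after[i] = stats.spearmanr(after.values[i], partner.values[i]).statistic
    finite = np.isfinite(r_before) & np.isfinite(r_after)
    deltas = np.where(finite, r_after - r_before, np.nan)
    ok = deltas[finite]
    frac_pos = float(np.mean(ok > 0)) if ok.size else 0.0
    if ok.size >= 2 and np.ptp(ok) > 0:
        t = stats.ttest_rel(r_after[finite], r_before[finite], alternative="greater")
        t_stat, p = float(t.statistic), float(t.pvalue)
    else:
        t_stat, p = float("nan"), float("nan")
    return ConcordanceResult(deltas, frac_pos, t_stat, p)
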