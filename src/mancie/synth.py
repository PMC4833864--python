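"""Paired synthetic datasets with shared signal, noise and column bias.

The generator emulates the data-generating premise the adjustment relies
on: two platforms measure the same biological sample structure, each with
its own noise, and the main platform additionally carries a technical bias
confined to a subset of samples.  Concretely:

* samples belong to ``k_clusters`` groups (balanced round-robin assignment,
  then shuffled);
* each main feature *i* has a latent signal ``s_i`` with one Gaussian mean
  per cluster (``signal_sd``), shared by that feature and its assigned
  associated partners;
* both matrices add independent Gaussian platform noise (``noise_sd``);
* ``n_biased_samples`` main-matrix columns receive an additive Gaussian
  scalar offset (``bias_sd``) shared by all features in the column — a
  batch-like column effect that turns those samples into outliers in
  sample space, exactly the structure the adjustment corrects;
* coordinates put each latent unit (one gene plus its partner peaks) in
  its own genomic window, windows tiled every ``10 * max_distance`` so
  neighbor search can never leak across units.

Gene annotations anchor at the TSS (+ strand, anchor = start); peak
annotations anchor at the interval midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import OmicsMatrix
from .matching import ANCHOR_MIDPOINT, ANCHOR_TSS, DEFAULT_MAX_DISTANCE, FeatureAnnotation

_PEAK_WIDTH = 150
_GENE_LENGTH = 500


@dataclass
class SyntheticDataset:
    """Paired matrices, annotations, ground truth and generator record."""

    main: OmicsMatrix
    assoc: OmicsMatrix
    main_annot: dict[str, FeatureAnnotation]
    assoc_annot: dict[str, FeatureAnnotation]
    true_labels: np.ndarray
    bias_mask: np.ndarray
    generator_params: dict = field(default_factory=dict)


def generate_paired_dataset(
    n_samples: int = 60,
    n_main_features: int = 300,
    n_assoc_features: int | None = None,
    k_clusters: int = 4,
    signal_sd: float = 1.0,
    noise_sd: float = 0.5,
    n_biased_samples: int = 10,
    bias_sd: float = 2.0,
    neighbors_per_gene: int = 5,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    seed: int = 0,
) -> SyntheticDataset:
    """Draw one paired dataset; the seed fixes every random draw.

    ``n_assoc_features`` defaults to ``n_main_features * neighbors_per_gene``
    and, when given explicitly, is distributed as evenly as possible across
    the latent units.  Independent random streams are used for labels,
    signal, the two noise fields and the bias, so setting ``bias_sd = 0``
    reproduces the unbiased columns of a biased generation bit for bit.
    """
    if k_clusters > n_samples:
        raise ValueError("k_clusters cannot exceed n_samples")
    if n_biased_samples > n_samples:
        raise ValueError("n_biased_samples cannot exceed n_samples")
    if min(signal_sd, noise_sd, bias_sd) < 0:
        raise ValueError("standard deviations must be >= 0")
    if n_main_features < 1 or n_samples < 3:
        raise ValueError("need >= 1 main feature and >= 3 samples")
    if neighbors_per_gene < 1:
        raise ValueError("neighbors_per_gene must be >= 1")
    if n_assoc_features is None:
        n_assoc_features = n_main_features * neighbors_per_gene
    if n_assoc_features < n_main_features:
        raise ValueError("need at least one associated feature per main feature")

    ss = np.random.SeedSequence(seed)
    rng_labels, rng_signal, rng_mnoise, rng_anoise, rng_bias = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    labels = np.arange(n_samples) % k_clusters
    labels = rng_labels.permutation(labels)

    # latent per-cluster means, expanded to per-sample signal rows
    cluster_means = rng_signal.normal(0.0, signal_sd, (n_main_features, k_clusters))
    signal = cluster_means[:, labels]  # (n_main, n_samples)

    main_vals = signal + rng_mnoise.normal(0.0, noise_sd, signal.shape)

    # distribute associated features across latent units as evenly as possible
    base, extra = divmod(n_assoc_features, n_main_features)
    partners_per_unit = [base + (1 if u < extra else 0) for u in range(n_main_features)]

    assoc_rows = np.empty((n_assoc_features, n_samples))
    unit_of_assoc = np.repeat(np.arange(n_main_features), partners_per_unit)
    assoc_noise = rng_anoise.normal(0.0, noise_sd, assoc_rows.shape)
    assoc_rows = signal[unit_of_assoc, :] + assoc_noise

    bias_mask = np.zeros(n_samples, dtype=bool)
    bias_mask[:n_biased_samples] = True
    bias = rng_bias.normal(0.0, bias_sd, n_biased_samples)
    main_vals[:, bias_mask] += bias  # same scalar per column, across features

    # genomic layout: one window per latent unit, far beyond neighbor reach
    tile = 10 * max_distance
    main_annot: dict[str, FeatureAnnotation] = {}
    assoc_annot: dict[str, FeatureAnnotation] = {}
    gene_ids = [f"gene_{u}" for u in range(n_main_features)]
    peak_ids = [f"peak_{j}" for j in range(n_assoc_features)]
    for u, gid in enumerate(gene_ids):
        tss = u * tile + max_distance  # leaves room for partners on both sides
        main_annot[gid] = FeatureAnnotation.with_anchor(
            gid, "chr1", tss, tss + _GENE_LENGTH, "+", ANCHOR_TSS
        )
    j = 0
    for u, count in enumerate(partners_per_unit):
        tss = u * tile + max_distance
        for p in range(count):
            # partners fan out from the TSS, always within max_distance
            offset = (p + 1) * min(2000, max(1, max_distance // (count + 1)))
            centre = tss + (offset if p % 2 == 0 else -offset)
            start = centre - _PEAK_WIDTH // 2
            assoc_annot[peak_ids[j]] = FeatureAnnotation.with_anchor(
                peak_ids[j], "chr1", start, start + _PEAK_WIDTH, "unknown", ANCHOR_MIDPOINT
            )
            j += 1

    sample_ids = [f"sample_{s}" for s in range(n_samples)]
    params = dict(
        n_samples=n_samples,
        n_main_features=n_main_features,
        n_assoc_features=n_assoc_features,
        k_clusters=k_clusters,
        signal_sd=signal_sd,
        noise_sd=noise_sd,
        n_biased_samples=n_biased_samples,
        bias_sd=bias_sd,
        neighbors_per_gene=neighbors_per_gene,
        max_distance=max_distance,
        seed=seed,
    )
    return SyntheticDataset(
        main=OmicsMatrix(gene_ids, sample_ids, main_vals),
        assoc=OmicsMatrix(peak_ids, sample_ids, assoc_rows),
        main_annot=main_annot,
        assoc_annot=assoc_annot,
        true_labels=labels,
        bias_mask=bias_mask,
        generator_params=params,
    )


def generate_concordance_triple(
    n_samples: int = 60,
    n_features: int = 300,
    k_clusters: int = 4,
    signal_sd: float = 1.0,
    noise_sd: float = 0.5,
    n_biased_samples: int = 10,
    bias_sd: float = 2.0,
    seed: int = 0,
) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix, np.ndarray, np.ndarray]:
    """Three one-to-one matched matrices sharing a latent signal.

    Emulates the expression/copy-number concordance setting: ``main`` is a
    noisy, partially biased measurement (e.g. expression on one platform),
    ``assoc`` an independent noisy replicate of the same signal (the same
    quantity on a second platform, used for adjustment), and ``partner`` a
    third independent noisy measurement of the signal (e.g. copy number),
    held out to score per-feature concordance before vs. after adjustment.
    All three share feature and sample IDs, so adjustment runs in matched
    (summarization-free) mode.  Returns
    ``(main, assoc, partner, true_labels, bias_mask)``.
    """
    if k_clusters > n_samples or n_biased_samples > n_samples:
        raise ValueError("cluster/bias counts cannot exceed n_samples")
    ss = np.random.SeedSequence(seed)
    rng_labels, rng_signal, rng_m, rng_a, rng_p, rng_bias = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    labels = rng_labels.permutation(np.arange(n_samples) % k_clusters)
    means = rng_signal.normal(0.0, signal_sd, (n_features, k_clusters))
    signal = means[:, labels]
    main_vals = signal + rng_m.normal(0.0, noise_sd, signal.shape)
    assoc_vals = signal + rng_a.normal(0.0, noise_sd, signal.shape)
    partner_vals = signal + rng_p.normal(0.0, noise_sd, signal.shape)
    bias_mask = np.zeros(n_samples, dtype=bool)
    bias_mask[:n_biased_samples] = True
    main_vals[:, bias_mask] += rng_bias.normal(0.0, bias_sd, n_biased_samples)
    fids = [f"gene_{i}" for i in range(n_features)]
    sids = [f"sample_{s}" for s in range(n_samples)]
    return (
        OmicsMatrix(fids, sids, main_vals),
        OmicsMatrix(list(fids), sids, assoc_vals),
        OmicsMatrix(list(fids), sids, partner_vals),
        labels,
        bias_mask,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write matrices, BED annotations, labels and the parameter record."""
    import json

    from .io import write_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "main": outdir / "main.tsv",
        "assoc": outdir / "assoc.tsv",
        "main_annot": outdir / "main_annot.bed",
        "assoc_annot": outdir / "assoc_annot.bed",
        "labels": outdir / "labels.tsv",
        "params": outdir / "params.json",
    }
    write_matrix(ds.main, paths["main"])
    write_matrix(ds.assoc, paths["assoc"])
    for key, annot in (("main_annot", ds.main_annot), ("assoc_annot", ds.assoc_annot)):
        with open(paths[key], "w") as fh:
            for ann in annot.values():
                strand = ann.strand if ann.strand in ("+", "-") else "."
                fh.write(
                    f"{ann.chromosome}\t{ann.start}\t{ann.end}\t{ann.feature_id}\t0\t{strand}\n"
                )
    with open(paths["labels"], "w") as fh:
        fh.write("sample_id\tcluster\tbiased\n")
        for sid, lab, b in zip(ds.main.sample_ids, ds.true_labels, ds.bias_mask):
            fh.write(f"{sid}\t{lab}\t{int(b)}\n")
    with open(paths["params"], "w") as fh:
        json.dump(ds.generator_params, fh, indent=2)
    return paths
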