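"""Feature correspondence between the main and associated matrices.

When the two matrices measure different feature spaces (genes vs. open
chromatin peaks, say) each main row is paired with the associated features
that are physically nearby in the genome: for a gene, the peaks within a
window around its transcription start site; for a peak, the genes whose TSS
falls near the peak centre.  The selected neighbor rows are then reduced to
a single summary row — the leading principal component of their correlation
matrix, sign-aligned with the main row — producing a summarized associated
matrix with exactly the main matrix's shape.

Anchors: genes are anchored at the strand-aware TSS (interval start on the
+ strand, end on the -), interval features at the integer midpoint
``floor((start + end) / 2)``.  Coordinates follow the BED convention
(0-based, half-open).

Defaults follow common practice for regulatory-element assignment: up to 50
peaks within 100 kb when summarizing a peak matrix around genes, up to 20
genes when summarizing a gene matrix around peaks (same 100 kb cap,
overridable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import DegenerateRowError, OmicsMatrix, first_pc_rows

logger = logging.getLogger("mancie")

DEFAULT_MAX_DISTANCE = 100_000
DEFAULT_MAX_NEIGHBORS_PEAKS_AROUND_GENES = 50
DEFAULT_MAX_NEIGHBORS_GENES_AROUND_PEAKS = 20

ANCHOR_TSS = "tss"
ANCHOR_MIDPOINT = "midpoint"


@dataclass(frozen=True)
class FeatureAnnotation:
    """Genomic anchor for one matrix row.

    ``anchor`` is the single coordinate used for distance computations:
    the strand-aware TSS for gene-like features, the interval midpoint for
    peak-like features.
    """

    feature_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "unknown"
    anchor: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for "
                f"{self.feature_id!r}"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @staticmethod
    def with_anchor(
        feature_id: str,
        chromosome: str,
        start: int,
        end: int,
        strand: str = "unknown",
        anchor_rule: str = ANCHOR_MIDPOINT,
    ) -> "FeatureAnnotation":
        """Build an annotation computing the anchor from the rule."""
        if anchor_rule == ANCHOR_TSS:
            anchor = end if strand == "-" else start
        elif anchor_rule == ANCHOR_MIDPOINT:
            anchor = (start + end) // 2
        else:
            raise ValueError(f"unknown anchor rule {anchor_rule!r}")
        return FeatureAnnotation(feature_id, chromosome, start, end, strand, anchor)


@dataclass
class NeighborMap:
    """Per-main-feature ordered neighbor lists into the associated matrix.

    ``neighbors[fid]`` is a list of ``(assoc_row_index, distance_bp)``
    sorted nearest-first; an empty list means the main row has no usable
    neighbor and must be skipped during adjustment.
    """

    main_feature_ids: list[str]
    neighbors: dict[str, list[tuple[int, int]]]

    def skip_mask(self) -> np.ndarray:
        return np.array(
            [len(self.neighbors.get(f, [])) == 0 for f in self.main_feature_ids],
            dtype=bool,
        )


def build_neighbor_map(
    main_annot: dict[str, FeatureAnnotation],
    assoc_annot: dict[str, FeatureAnnotation],
    assoc_feature_ids: list[str],
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS_PEAKS_AROUND_GENES,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    main_feature_ids: list[str] | None = None,
) -> NeighborMap:
    """Select, per main feature, the nearest associated features.

    Candidates must share the main feature's chromosome and lie within
    ``max_distance`` base pairs (anchor to anchor); they are sorted by
    distance (ties: lower anchor coordinate, then lexicographic feature ID)
    and truncated to ``max_neighbors``.  Main features missing from
    ``main_annot`` get an empty list and a logged warning; associated rows
    missing from ``assoc_annot`` are simply never selected.
    """
    if max_neighbors < 1:
        raise ValueError("max_neighbors must be >= 1")
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    if not assoc_annot or not main_annot:
        raise ValueError("annotation sets must be non-empty")
    if main_feature_ids is None:
        main_feature_ids = sorted(main_annot)

    # per-chromosome sorted anchor arrays for the associated side
    by_chrom: dict[str, list[tuple[int, str, int]]] = {}
    for idx, fid in enumerate(assoc_feature_ids):
        ann = assoc_annot.get(fid)
        if ann is None:
            continue
        by_chrom.setdefault(ann.chromosome, []).append((ann.anchor, fid, idx))
    for entries in by_chrom.values():
        entries.sort()
    chrom_anchors = {
        ch: np.array([e[0] for e in entries])
        for ch, entries in by_chrom.items()
    }

    neighbors: dict[str, list[tuple[int, int]]] = {}
    missing: list[str] = []
    for fid in main_feature_ids:
        ann = main_annot.get(fid)
        if ann is None:
            neighbors[fid] = []
            missing.append(fid)
            continue
        entries = by_chrom.get(ann.chromosome)
        if not entries:
            neighbors[fid] = []
            continue
        anchors = chrom_anchors[ann.chromosome]
        lo = int(np.searchsorted(anchors, ann.anchor - max_distance, "left"))
        hi = int(np.searchsorted(anchors, ann.anchor + max_distance, "right"))
        cands = [
            (abs(a - ann.anchor), a, nfid, idx)
            for a, nfid, idx in entries[lo:hi]
        ]
        cands.sort(key=lambda t: (t[0], t[1], t[2]))
        neighbors[fid] = [(idx, d) for d, _, _, idx in cands[:max_neighbors]]
    if missing:
        logger.warning(
            "%d main feature(s) missing from annotation, skipped: %s",
            len(missing),
            ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""),
        )
    return NeighborMap(list(main_feature_ids), neighbors)


def summarize_associated(
    assoc: OmicsMatrix, nmap: NeighborMap, main: OmicsMatrix
) -> tuple[OmicsMatrix, np.ndarray]:
    """Reduce neighbor sub-matrices to one summary row per main feature.

    Each non-empty neighbor set is collapsed to the score vector of the
    leading PC of its correlation matrix (sign-aligned with the main row).
    Returns the summarized matrix, shaped exactly like ``main``, and the
    boolean skip mask (True where no usable neighbor exists); skipped rows
    carry zeros as placeholders and are never touched by the adjustment.
    """
    if nmap.main_feature_ids != main.feature_ids:
        raise ValueError("neighbor map feature order must match the main matrix")
    out = np.zeros_like(main.values)
    skip = nmap.skip_mask().copy()
    for i, fid in enumerate(main.feature_ids):
        idxs = [idx for idx, _ in nmap.neighbors.get(fid, [])]
        if not idxs:
            continue
        sub = assoc.values[idxs, :]
        try:
            out[i] = first_pc_rows(sub, reference=main.values[i])
        except DegenerateRowError:
            skip[i] = True
            logger.warning("all neighbors of %r are degenerate; row skipped", fid)
    summarized = OmicsMatrix(list(main.feature_ids), list(main.sample_ids), out)
    return summarized, skip


def detect_row_matching(main: OmicsMatrix, assoc: OmicsMatrix) -> str:
    """Return ``"matched"`` iff the two feature ID sets are identical.

    In matched mode the caller reorders the associated rows to the main
    order and bypasses neighbor summarization entirely (one-to-one feature
    correspondence, e.g. expression and copy number of the same genes).
    """
    return "matched" if set(main.feature_ids) == set(assoc.feature_ids) else "unmatched"


def reorder_to_main(main: OmicsMatrix, assoc: OmicsMatrix) -> OmicsMatrix:
    """Row-reorder a one-to-one matched associated matrix to main's order."""
    if detect_row_matching(main, assoc) != "matched":
        raise ValueError("feature ID sets differ; cannot reorder one-to-one")
    pos = {f: i for i, f in enumerate(assoc.feature_ids)}
    order = [pos[f] for f in main.feature_ids]
    return OmicsMatrix(
        list(main.feature_ids), list(assoc.sample_ids), assoc.values[order, :]
    )
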