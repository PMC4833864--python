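"""Matrix and annotation I/O plus run configuration.

Matrices are dense tab-separated text: first row sample IDs, first column
feature IDs, numeric body.  Annotations are BED-like TSV: chromosome,
start, end, feature_id, [score, ignored], [strand]; ``#`` comment lines
are skipped.  Output mirrors the input dialect, with floats written to 12
significant digits so round trips are stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CutoffConfig, OmicsMatrix
from .matching import (
    ANCHOR_MIDPOINT,
    DEFAULT_MAX_DISTANCE,
    DEFAULT_MAX_NEIGHBORS_PEAKS_AROUND_GENES,
    FeatureAnnotation,
)


def read_matrix(path: str | Path) -> OmicsMatrix:
    """Read a feature-by-sample TSV matrix, validating IDs and numerics.

    Duplicate feature or sample IDs, ragged rows, empty matrices and
    non-numeric cells are rejected with the offending coordinates named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty matrix")
    feats = [str(i) for i in df.index]
    samples = [str(c) for c in df.columns]
    dup = _first_duplicate(feats)
    if dup is not None:
        raise ValueError(f"{path}: duplicate feature ID {dup!r}")
    dup = _first_duplicate(samples)
    if dup is not None:
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at row {feats[i]!r}, column {samples[j]!r}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {df.iat[i, j]!r} at row "
            f"{feats[i]!r}, column {samples[j]!r}"
        )
    return OmicsMatrix(feats, samples, numeric.to_numpy(dtype=float))


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with 12-significant-digit floats."""
    matrix.to_dataframe().to_csv(Path(path), sep="\t", float_format="%.12g")


def _first_duplicate(ids: list[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_annotations(
    path: str | Path, anchor_rule: str = ANCHOR_MIDPOINT
) -> dict[str, FeatureAnnotation]:
    """Read BED-like annotations into a feature_id -> annotation mapping.

    Columns: chromosome, start, end, feature_id, optional score (ignored),
    optional strand.  Duplicate feature IDs are a hard error — silently
    picking one record risks matching the wrong genomic location.
    """
    path = Path(path)
    out: dict[str, FeatureAnnotation] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected >= 4 columns")
            chrom, start, end, fid = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "unknown"
            if fid in out:
                raise ValueError(f"{path}:{ln}: duplicate feature ID {fid!r}")
            out[fid] = FeatureAnnotation.with_anchor(
                fid, chrom, start, end, strand, anchor_rule
            )
    if not out:
        raise ValueError(f"{path}: no annotation records")
    return out


def validate_pair(main: OmicsMatrix, assoc: OmicsMatrix) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Enforce the matched-column contract, reordering assoc if needed.

    The two matrices must profile exactly the same samples; a shuffled but
    equal sample set is accepted and the associated columns are reordered
    to the main order.  A set mismatch is a hard error listing the
    symmetric difference.
    """
    a, b = set(main.sample_ids), set(assoc.sample_ids)
    if a != b:
        only_main = sorted(a - b)
        only_assoc = sorted(b - a)
        raise ValueError(
            "sample sets differ: "
            f"only in main {only_main}, only in associated {only_assoc}"
        )
    if main.sample_ids == assoc.sample_ids:
        return main, assoc
    pos = {s: j for j, s in enumerate(assoc.sample_ids)}
    order = [pos[s] for s in main.sample_ids]
    reordered = OmicsMatrix(
        list(assoc.feature_ids), list(main.sample_ids), assoc.values[:, order]
    )
    return main, reordered


@dataclass
class RunConfig:
    """Everything an end-to-end run needs.

    ``cutoff2_mode``: ``"fixed"`` uses ``cutoffs.cutoff2`` as given;
    ``"empirical-third"`` replaces it with the empirical quantile that puts
    roughly ``scenario3_target`` of the non-skipped rows into scenario 3.
    """

    main_path: str | Path = ""
    assoc_path: str | Path = ""
    main_annot_path: str | Path | None = None
    assoc_annot_path: str | Path | None = None
    cutoffs: CutoffConfig = field(default_factory=CutoffConfig)
    cutoff2_mode: str = "fixed"  # "fixed" | "empirical-third"
    scenario3_target: float = 1.0 / 3.0
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS_PEAKS_AROUND_GENES
    max_distance: int = DEFAULT_MAX_DISTANCE
    anchor_main: str = ANCHOR_MIDPOINT
    anchor_assoc: str = ANCHOR_MIDPOINT
    seed: int = 0
    out_path: str | Path | None = None
    diagnostics_path: str | Path | None = None

    def __post_init__(self) -> None:
        if self.cutoff2_mode not in ("fixed", "empirical-third"):
            raise ValueError(f"unknown cutoff2 mode {self.cutoff2_mode!r}")

    def validate_paths(self) -> None:
        for p in (self.main_path, self.assoc_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for p in (self.main_annot_path, self.assoc_annot_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
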