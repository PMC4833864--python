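"""End-to-end orchestration: load, validate, match/summarize, adjust, write.

``run_mancie`` wires the modules together: read the two matrices, enforce
the matched-column contract, detect whether features correspond one-to-one
(bypassing summarization) or need neighbor matching via annotations, pick
the empirical cutoff2 if requested, adjust every row, and write the
adjusted matrix plus per-feature diagnostics.  Outputs are written only
after the whole computation succeeds, so a failed run never leaves partial
files behind.
"""

from __future__ import annotations

import hashlib
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    AdjustmentResult,
    CutoffConfig,
    DegenerateRowError,
    OmicsMatrix,
    adjust_matrix,
    pearson_correlation,
    select_cutoff2,
)
from .io import RunConfig, read_annotations, read_matrix, validate_pair, write_matrix
from .matching import (
    build_neighbor_map,
    detect_row_matching,
    reorder_to_main,
    summarize_associated,
)

logger = logging.getLogger("mancie")


@dataclass
class RunReport:
    """Summary of one adjustment run."""

    scenario_counts: dict[str, int]
    n_skipped: int
    cutoff1: float
    cutoff2: float
    cutoff2_mode: str
    matching_mode: str
    runtime_seconds: float
    input_shapes: dict[str, tuple[int, int]]
    input_checksums: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.scenario_counts.values())
        n_main = self.input_shapes["main"][0]
        if total != n_main:
            raise ValueError(
                f"scenario counts sum to {total}, expected {n_main} rows"
            )


def _checksum(values: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(values).tobytes()).hexdigest()[:16]


def _row_correlations(
    main: OmicsMatrix, summarized: OmicsMatrix, skip_mask: np.ndarray
) -> np.ndarray:
    rho = np.full(main.n_features, np.nan)
    for i in range(main.n_features):
        if skip_mask[i]:
            continue
        try:
            rho[i] = pearson_correlation(summarized.values[i], main.values[i])
        except DegenerateRowError:
            pass
    return rho


def adjust_pair(
    main: OmicsMatrix,
    assoc: OmicsMatrix,
    main_annot=None,
    assoc_annot=None,
    cutoffs: CutoffConfig = CutoffConfig(),
    cutoff2_mode: str = "fixed",
    scenario3_target: float = 1.0 / 3.0,
    max_neighbors: int = 50,
    max_distance: int = 100_000,
) -> tuple[AdjustmentResult, RunReport]:
    """In-memory end-to-end adjustment (the core of :func:`run_mancie`)."""
    t0 = time.perf_counter()
    main, assoc = validate_pair(main, assoc)
    mode = detect_row_matching(main, assoc)
    if mode == "matched":
        summarized = reorder_to_main(main, assoc)
        skip_mask = np.zeros(main.n_features, dtype=bool)
    else:
        if main_annot is None or assoc_annot is None:
            raise ValueError(
                "feature IDs do not correspond one-to-one; provide annotations "
                "for both matrices to enable neighbor matching"
            )
        nmap = build_neighbor_map(
            main_annot,
            assoc_annot,
            assoc.feature_ids,
            max_neighbors=max_neighbors,
            max_distance=max_distance,
            main_feature_ids=main.feature_ids,
        )
        summarized, skip_mask = summarize_associated(assoc, nmap, main)
    logger.info("matching mode: %s (%d rows skipped)", mode, int(skip_mask.sum()))

    if cutoff2_mode == "empirical-third":
        rho = _row_correlations(main, summarized, skip_mask)
        c2 = select_cutoff2(rho, scenario3_target)
        if c2 <= cutoffs.cutoff1:
            warnings.warn(
                "empirical cutoff2 fell at or below cutoff1; clamping",
                RuntimeWarning,
            )
            c2 = cutoffs.cutoff1 + 1e-12
        cutoffs = CutoffConfig(cutoffs.cutoff1, c2)
        logger.info("empirical cutoff2 = %.4f", c2)

    result = adjust_matrix(main, summarized, cutoffs, skip_mask)
    counts = result.scenario_counts()
    report = RunReport(
        scenario_counts=counts,
        n_skipped=counts["skipped"],
        cutoff1=cutoffs.cutoff1,
        cutoff2=cutoffs.cutoff2,
        cutoff2_mode=cutoff2_mode,
        matching_mode=mode,
        runtime_seconds=time.perf_counter() - t0,
        input_shapes={
            "main": main.values.shape,
            "assoc": assoc.values.shape,
        },
        input_checksums={
            "main": _checksum(main.values),
            "assoc": _checksum(assoc.values),
        },
    )
    return result, report


def run_mancie(cfg: RunConfig) -> tuple[AdjustmentResult, RunReport]:
    """File-driven run: load inputs per ``cfg``, adjust, write outputs."""
    cfg.validate_paths()
    main = read_matrix(cfg.main_path)
    assoc = read_matrix(cfg.assoc_path)
    main_annot = (
        read_annotations(cfg.main_annot_path, cfg.anchor_main)
        if cfg.main_annot_path
        else None
    )
    assoc_annot = (
        read_annotations(cfg.assoc_annot_path, cfg.anchor_assoc)
        if cfg.assoc_annot_path
        else None
    )
    result, report = adjust_pair(
        main,
        assoc,
        main_annot=main_annot,
        assoc_annot=assoc_annot,
        cutoffs=cfg.cutoffs,
        cutoff2_mode=cfg.cutoff2_mode,
        scenario3_target=cfg.scenario3_target,
        max_neighbors=cfg.max_neighbors,
        max_distance=cfg.max_distance,
    )
    if cfg.out_path:
        write_matrix(result.adjusted, cfg.out_path)
    if cfg.diagnostics_path:
        write_diagnostics(result, cfg.diagnostics_path)
    return result, report


def write_diagnostics(result: AdjustmentResult, path: str | Path) -> None:
    """Per-feature TSV: feature_id, rho, scenario."""
    with open(path, "w") as fh:
        fh.write("feature_id\trho\tscenario\n")
        for fid, r, s in zip(
            result.adjusted.feature_ids, result.row_correlation, result.scenario
        ):
            r_str = "NA" if not np.isfinite(r) else f"{r:.12g}"
            fh.write(f"{fid}\t{r_str}\t{s}\n")
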