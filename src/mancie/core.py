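"""Row-wise adjustment mathematics.

The method adjusts a "main" feature-by-sample matrix M row by row using a
column-matched "associated" matrix C (already summarized to M's feature
space, see :mod:`mancie.matching`).  For each row pair ``(m_i, c_i)`` the
Pearson correlation ``rho`` gates one of three update regimes:

* scenario 1 (``rho <= cutoff1``): the row is kept unchanged;
* scenario 2 (``cutoff1 < rho <= cutoff2``): a correlation-weighted sum
  ``scale(m) + rho * scale(c)`` of the standardized rows;
* scenario 3 (``rho > cutoff2``): the first principal component of the two
  standardized rows, computed on their 2x2 Pearson correlation matrix and
  sign-aligned with the original row.

Whatever the regime, the updated row is rescaled to the mean and standard
deviation of the original row, so per-row first and second moments are
conserved exactly and only the *pattern across samples* changes.

Standardization conventions used throughout the package: rows are centred
to mean 0 and scaled to s.d. 1, with the sample (n-1 denominator) standard
deviation.  The denominator choice only affects intermediate vectors up to
an overall positive factor, which the final rescaling absorbs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger("mancie")

#: Relative variance threshold below which a row counts as constant
#: (variance <= DEGENERATE_REL_TOL * mean-square of the row).
DEGENERATE_REL_TOL = 1e-12

SCENARIO_SKIPPED = "skipped"
SCENARIO_1 = "scenario1"
SCENARIO_2 = "scenario2"
SCENARIO_3 = "scenario3"
SCENARIOS = (SCENARIO_SKIPPED, SCENARIO_1, SCENARIO_2, SCENARIO_3)


class DegenerateRowError(ValueError):
    """A row vector has (numerically) zero variance."""


@dataclass
class OmicsMatrix:
    """A feature-by-sample numeric matrix with feature and sample IDs.

    Parameters
    ----------
    feature_ids : list of str
        Unique row identifiers (genes, peaks, probes ...).
    sample_ids : list of str
        Unique column identifiers; two matrices passed to the adjustment
        must carry identical sample IDs in identical order.
    values : ndarray of shape (n_features, n_samples)
        Dense numeric matrix; non-finite entries are rejected.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        nf, ns = self.values.shape
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.feature_ids) != nf:
            raise ValueError(
                f"{len(self.feature_ids)} feature IDs for {nf} rows"
            )
        if len(self.sample_ids) != ns:
            raise ValueError(
                f"{len(self.sample_ids)} sample IDs for {ns} columns"
            )
        if len(set(self.feature_ids)) != nf:
            raise ValueError("duplicate feature IDs")
        if len(set(self.sample_ids)) != ns:
            raise ValueError("duplicate sample IDs")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite value at row "
                f"{self.feature_ids[bad[0]]!r}, column {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(
            list(self.feature_ids), list(self.sample_ids), self.values.copy()
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_dataframe(cls, df) -> "OmicsMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class CutoffConfig:
    """Correlation cutoffs gating the three update scenarios.

    Defaults (0, 0.5) assume that only positive main/associated correlation
    is biologically meaningful (cutoff1 = 0) and that strong concordance
    (rho > 0.5) justifies full principal-component replacement.
    """

    cutoff1: float = 0.0
    cutoff2: float = 0.5

    def __post_init__(self) -> None:
        for name in ("cutoff1", "cutoff2"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [-1, 1]")
        if not self.cutoff1 < self.cutoff2:
            raise ValueError(
                f"cutoff1 ({self.cutoff1}) must be < cutoff2 ({self.cutoff2})"
            )


@dataclass
class AdjustmentResult:
    """Adjusted matrix plus per-row diagnostics.

    ``row_correlation`` holds the Pearson correlation between each main row
    and its (summarized) associated row; NaN marks skipped rows.
    ``scenario`` holds one label per row from
    ``{"skipped", "scenario1", "scenario2", "scenario3"}``.
    """

    adjusted: OmicsMatrix
    row_correlation: np.ndarray
    scenario: list[str]

    def scenario_counts(self) -> dict[str, int]:
        return {s: self.scenario.count(s) for s in SCENARIOS}


# ---------------------------------------------------------------------------
# elementary row operations
# ---------------------------------------------------------------------------

def _is_degenerate(x: np.ndarray) -> bool:
    x = np.asarray(x, dtype=float)
    ms = float(np.mean(x * x))
    return float(np.var(x)) <= DEGENERATE_REL_TOL * max(ms, 1.0)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if _is_degenerate(x) or _is_degenerate(y):
        raise DegenerateRowError("zero-variance input to correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return min(1.0, max(-1.0, r))


def scale_row(x: Sequence[float]) -> np.ndarray:
    """Standardize a row vector: (x - mean) / sd, sample s.d. (ddof=1)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("x must be a 1-D vector of length >= 2")
    if _is_degenerate(x):
        raise DegenerateRowError("zero-variance row cannot be standardized")
    return (x - x.mean()) / x.std(ddof=1)


def rescale_to(x: Sequence[float], target_mean: float, target_sd: float) -> np.ndarray:
    """Rescale a vector to a target mean and (sample) standard deviation."""
    if target_sd <= 0:
        raise ValueError("target_sd must be positive")
    return scale_row(x) * target_sd + target_mean


def first_pc_rows(rows: np.ndarray, reference: Sequence[float]) -> np.ndarray:
    """Score vector of the leading PC of a row set, on the correlation matrix.

    Each row is standardized, the k x k Pearson correlation matrix of the
    rows is eigendecomposed, and the score vector over the n samples is the
    leading-eigenvector-weighted sum of the standardized rows.  The result
    is negated if its Pearson correlation with ``reference`` is negative, so
    the summary always points the same way as the row it will adjust.

    Degenerate (constant) rows are dropped; if all rows are degenerate a
    :class:`DegenerateRowError` is raised.  For a single usable row the
    result is its standardization, sign-aligned to the reference.

    Near-ties among leading eigenvalues are broken deterministically: among
    eigenvectors within relative tolerance of the top eigenvalue, the score
    vector with the largest absolute correlation with the reference wins,
    exact ties falling to the lowest eigenvector index.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    reference = np.asarray(reference, dtype=float)
    if rows.shape[1] != reference.size:
        raise ValueError("rows and reference must share sample dimension")
    if rows.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    usable = [i for i in range(rows.shape[0]) if not _is_degenerate(rows[i])]
    if not usable:
        raise DegenerateRowError("all rows are constant")
    z = np.vstack([scale_row(rows[i]) for i in usable])
    if z.shape[0] == 1:
        score = z[0]
    else:
        n = z.shape[1]
        corr = (z @ z.T) / (n - 1)
        evals, evecs = np.linalg.eigh(corr)
        top = evals[-1]
        tol = 1e-9 * max(abs(top), 1.0)
        candidates = [j for j in range(len(evals)) if evals[j] >= top - tol]
        best_score, best_abs = None, -1.0
        for j in candidates:
            s = evecs[:, j] @ z
            if _is_degenerate(s):
                a = -1.0  # a zero score vector never wins over a real one
            else:
                a = abs(pearson_correlation(s, reference))
            if a > best_abs + 1e-15:
                best_abs, best_score = a, s
        score = best_score
    if _is_degenerate(score):
        raise DegenerateRowError("principal-component score is constant")
    if pearson_correlation(score, reference) < 0:
        score = -score
    return score


# ---------------------------------------------------------------------------
# the three-scenario update
# ---------------------------------------------------------------------------

def adjust_row(
    m: Sequence[float], c: Sequence[float], cfg: CutoffConfig = CutoffConfig()
) -> tuple[np.ndarray, str]:
    """Adjust one main row using its associated row.

    Returns ``(adjusted_row, scenario_label)``.  Degenerate inputs return
    the main row unchanged with the label ``"skipped"``.
    """
    m = np.asarray(m, dtype=float)
    c = np.asarray(c, dtype=float)
    try:
        rho = pearson_correlation(c, m)
    except DegenerateRowError:
        return m.copy(), SCENARIO_SKIPPED
    if rho <= cfg.cutoff1:
        return m.copy(), SCENARIO_1
    mean, sd = float(m.mean()), float(m.std(ddof=1))
    if rho <= cfg.cutoff2:
        mixed = scale_row(m) + rho * scale_row(c)
        return rescale_to(mixed, mean, sd), SCENARIO_2
    pc = first_pc_rows(np.vstack([m, c]), reference=m)
    return rescale_to(pc, mean, sd), SCENARIO_3


def adjust_matrix(
    main: OmicsMatrix,
    assoc_summarized: OmicsMatrix,
    cfg: CutoffConfig = CutoffConfig(),
    skip_mask: np.ndarray | None = None,
) -> AdjustmentResult:
    """Apply the three-scenario update independently to every main row.

    ``assoc_summarized`` must already match ``main`` in shape and sample
    order (one summarized associated row per main row); ``skip_mask`` marks
    rows with no usable associated counterpart, which pass through
    unchanged.
    """
    if main.values.shape != assoc_summarized.values.shape:
        raise ValueError(
            f"shape mismatch: main {main.values.shape} vs "
            f"associated {assoc_summarized.values.shape}"
        )
    for j, (a, b) in enumerate(zip(main.sample_ids, assoc_summarized.sample_ids)):
        if a != b:
            raise ValueError(
                f"sample order mismatch at column {j}: {a!r} vs {b!r}"
            )
    if skip_mask is None:
        skip_mask = np.zeros(main.n_features, dtype=bool)
    skip_mask = np.asarray(skip_mask, dtype=bool)
    if skip_mask.shape != (main.n_features,):
        raise ValueError("skip_mask length must equal the number of main rows")

    out = main.values.copy()
    rho = np.full(main.n_features, np.nan)
    labels: list[str] = []
    skipped_ids: list[str] = []
    for i in range(main.n_features):
        if skip_mask[i]:
            labels.append(SCENARIO_SKIPPED)
            continue
        row, label = adjust_row(main.values[i], assoc_summarized.values[i], cfg)
        out[i] = row
        labels.append(label)
        if label == SCENARIO_SKIPPED:
            skipped_ids.append(main.feature_ids[i])
        else:
            rho[i] = pearson_correlation(
                assoc_summarized.values[i], main.values[i]
            )
    if skipped_ids:
        logger.warning(
            "%d degenerate row(s) skipped: %s",
            len(skipped_ids),
            ", ".join(skipped_ids[:10]) + ("..." if len(skipped_ids) > 10 else ""),
        )
    adjusted = OmicsMatrix(list(main.feature_ids), list(main.sample_ids), out)
    return AdjustmentResult(adjusted, rho, labels)


def select_cutoff2(
    row_correlations: Sequence[float], target_fraction: float = 1.0 / 3.0
) -> float:
    """Empirical cutoff2 putting ~``target_fraction`` of rows in scenario 3.

    Returns the (1 - target_fraction) linear-interpolation quantile of the
    finite row correlations, so that roughly a third of rows (by default)
    exceed the cutoff and receive the full principal-component update.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0, 1)")
    r = np.asarray(row_correlations, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("no finite row correlations to select a cutoff from")
    return float(np.quantile(r, 1.0 - target_fraction, method="linear"))
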