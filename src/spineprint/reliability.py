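"""Edge-wise test-retest reliability via the one-way random ICC(1,1).

For one edge measured in k runs on Ns subjects,

    ICC(1,1) = (MSR - MSW) / (MSR + (k-1) * MSW)

with MSR the between-subject mean square (df Ns-1) and MSW the
within-subject mean square (df Ns*(k-1)).  For k = 2 the coefficient is
bounded in [-1, 1]; negative values are retained, not clipped.  Applied
independently to every edge and folded back into the symmetric N x N
layout (diagonal undefined), the map shows which connections are stable
across runs.  Thresholding the map at a high percentile keeps only the
most reliable edges; nodal strength sums (or averages) each ROI's row of
the thresholded map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import FCVector
from .parcellation import Parcellation, ROIS_PER_LEVEL


class ReliabilityError(ValueError):
    pass


def icc_1_1(measurements: np.ndarray) -> float:
    """One-way random-effects ICC for one edge (rows subjects, cols runs)."""
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ReliabilityError("measurements must be a 2-D subjects x runs table")
    ns, k = x.shape
    if ns < 2:
        raise ReliabilityError("ICC needs at least 2 subjects")
    if k < 2:
        raise ReliabilityError("ICC needs at least 2 measurements per subject")
    if not np.all(np.isfinite(x)):
        raise ReliabilityError("non-finite measurement values")
    subject_means = x.mean(axis=1)
    grand = x.mean()
    msr = k * np.sum((subject_means - grand) ** 2) / (ns - 1)
    msw = np.sum((x - subject_means[:, None]) ** 2) / (ns * (k - 1))
    denom = msr + (k - 1) * msw
    if denom == 0:
        return float("nan")
    return float((msr - msw) / denom)


@dataclass
class ICCMap:
    """Per-edge ICC(1,1) in N x N layout, with the underlying mean squares."""

    values: np.ndarray
    msr_map: np.ndarray
    msw_map: np.ndarray
    labels: Parcellation
    k: int = 2

    @property
    def N(self) -> int:
        return self.values.shape[0]


def icc_matrix(run1_vectors: list[FCVector], run2_vectors: list[FCVector]) -> ICCMap:
    """Edge-wise ICC(1,1) over the cohort's two runs, mapped back to N x N."""
    if len(run1_vectors) != len(run2_vectors):
        raise ReliabilityError("run-1 and run-2 cohorts differ in size")
    ns = len(run1_vectors)
    if ns < 2:
        raise ReliabilityError("ICC needs at least 2 subjects")
    ref = run1_vectors[0].edge_index
    for v in run1_vectors[1:] + run2_vectors:
        if v.edge_index != ref:
            raise ReliabilityError("mismatched edge indices across FC vectors")
    x1 = np.array([v.values for v in run1_vectors])  # Ns x M
    x2 = np.array([v.values for v in run2_vectors])
    k = 2
    subj_mean = (x1 + x2) / 2.0
    grand = subj_mean.mean(axis=0)
    msr = k * np.sum((subj_mean - grand) ** 2, axis=0) / (ns - 1)
    msw = np.sum((x1 - subj_mean) ** 2 + (x2 - subj_mean) ** 2, axis=0) / (ns * (k - 1))
    denom = msr + (k - 1) * msw
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (msr - msw) / denom, np.nan)

    parc = run1_vectors[0].labels
    n = parc.N
    values = np.full((n, n), np.nan)
    msr_m = np.full((n, n), np.nan)
    msw_m = np.full((n, n), np.nan)
    rows, cols = np.triu_indices(n, k=1)
    for arr, flat in ((values, icc), (msr_m, msr), (msw_m, msw)):
        arr[rows, cols] = flat
        arr[cols, rows] = flat
    return ICCMap(values=values, msr_map=msr_m, msw_map=msw_m, labels=parc, k=k)


def average_level_blocks(icc_maps: list[ICCMap]) -> np.ndarray:
    """Elementwise mean of all within-level 14 x 14 blocks across maps.

    Cross-level edges are excluded; undefined (NaN) entries are left out
    of each elementwise mean.
    """
    if not icc_maps:
        raise ReliabilityError("no ICC maps supplied")
    blocks = []
    for m in icc_maps:
        spinal_levels = m.labels.levels
        if not spinal_levels:
            raise ReliabilityError("ICC map has no spinal levels")
        for lv in spinal_levels:
            idx = m.labels.level_indices(lv)
            if idx.size != ROIS_PER_LEVEL:
                raise ReliabilityError(
                    f"level {lv} has {idx.size} ROIs; expected {ROIS_PER_LEVEL} "
                    "(canonical cross-section scheme required)")
            blocks.append(m.values[np.ix_(idx, idx)])
    stack = np.array(blocks)
    counts = np.sum(np.isfinite(stack), axis=0)
    sums = np.where(np.isfinite(stack), stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def threshold_percentile(matrix: np.ndarray, pct: float = 95.0
                         ) -> tuple[float, np.ndarray]:
    """Zero out entries below the pct-th percentile of the defined edges.

    The percentile is computed over the strict upper triangle only (each
    edge counted once, NaN excluded).  Returns (threshold, filtered
    matrix); the filtered matrix has zeros below threshold and on the
    diagonal/undefined entries.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ReliabilityError("matrix must be square")
    if not 0 < pct < 100:
        raise ReliabilityError("pct must lie strictly between 0 and 100")
    rows, cols = np.triu_indices(m.shape[0], k=1)
    edges = m[rows, cols]
    edges = edges[np.isfinite(edges)]
    if edges.size == 0:
        raise ReliabilityError("no defined edges to threshold")
    thr = float(np.percentile(edges, pct))
    filtered = np.where(np.isfinite(m) & (m >= thr), m, 0.0)
    np.fill_diagonal(filtered, 0.0)
    return thr, filtered


def nodal_strength(filtered: np.ndarray, mode: str = "sum") -> np.ndarray:
    """Per-ROI reliability: row reduction of the (thresholded) symmetric map.

    ``mode="sum"`` sums each row (diagonal excluded); ``mode="mean"``
    averages over the N-1 off-diagonal entries instead.
    """
    m = np.asarray(filtered, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ReliabilityError("matrix must be square")
    off = m.copy()
    np.fill_diagonal(off, 0.0)
    sums = off.sum(axis=1)
    if mode == "sum":
        return sums
    if mode == "mean":
        return sums / (m.shape[0] - 1)
    raise ReliabilityError(f"unknown nodal strength mode {mode!r}")
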