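"""Functional-connectivity matrices and their vectorized (edge) form.

Static FC is the Pearson correlation of each pair of parcel time series
over time.  For fingerprinting the strict upper triangle of the symmetric
N x N matrix is unfolded, in fixed row-major order, into an edge vector of
length M = N(N-1)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parcellation import ParcelledRun, Parcellation

SYMMETRY_TOL = 1e-10


class ConnectivityError(ValueError):
    pass


@dataclass
class FCMatrix:
    """Symmetric Pearson-correlation matrix for one subject/run."""

    values: np.ndarray
    labels: Parcellation
    subject_id: str
    run: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.labels.N
        if self.values.shape != (n, n):
            raise ConnectivityError(f"expected {n}x{n} matrix, got {self.values.shape}")


@dataclass
class FCVector:
    """Upper-triangle unfolding of an FC matrix.

    ``edge_index`` lists the (row, col) pairs, row < col, in row-major
    order; every vector produced from the same parcellation shares it.
    """

    values: np.ndarray
    edge_index: tuple[tuple[int, int], ...]
    labels: Parcellation
    subject_id: str
    run: int

    @property
    def M(self) -> int:
        return len(self.values)

    def edge_names(self) -> list[str]:
        names = self.labels.names
        return [f"{names[i]}|{names[j]}" for i, j in self.edge_index]


def compute_fc(run: ParcelledRun, fisher_z: bool = False) -> FCMatrix:
    """Pearson FC of a parcelled run; optional Fisher z-transform (off by
    default: fingerprints correlate raw FC profiles)."""
    data = run.data
    if data.shape[0] < 3:
        raise ConnectivityError("need at least 3 time points for FC")
    stds = data.std(axis=0)
    bad = np.flatnonzero(stds == 0)
    if bad.size:
        raise ConnectivityError(
            f"constant time series for ROI {run.labels.names[bad[0]]!r}"
        )
    fc = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(fc, 1.0)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    if fisher_z:
        off = ~np.eye(fc.shape[0], dtype=bool)
        fc[off] = np.arctanh(np.clip(fc[off], -1 + 1e-15, 1 - 1e-15))
    return FCMatrix(fc, run.labels, run.subject_id, run.run)


def edge_index_for(n: int) -> tuple[tuple[int, int], ...]:
    rows, cols = np.triu_indices(n, k=1)
    return tuple(zip(rows.tolist(), cols.tolist()))


def vectorize_fc(fc: FCMatrix) -> FCVector:
    """Unfold the strict upper triangle into a length N(N-1)/2 vector."""
    v = fc.values
    if not np.allclose(v, v.T, atol=SYMMETRY_TOL, rtol=0):
        raise ConnectivityError("FC matrix is not symmetric")
    n = v.shape[0]
    rows, cols = np.triu_indices(n, k=1)
    return FCVector(v[rows, cols].copy(), edge_index_for(n),
                    fc.labels, fc.subject_id, fc.run)


def devectorize_fc(vec: FCVector, diagonal: float = 1.0) -> FCMatrix:
    """Fold an edge vector back into the symmetric N x N layout."""
    n = vec.labels.N
    out = np.full((n, n), float(diagonal))
    rows, cols = np.triu_indices(n, k=1)
    out[rows, cols] = vec.values
    out[cols, rows] = vec.values
    return FCMatrix(out, vec.labels, vec.subject_id, vec.run)
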