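"""Identifiability matrix and fingerprint statistics.

Given two runs per subject, the identifiability matrix I (Ns x Ns,
asymmetric) holds the Pearson correlation between subject i's run-1 FC
vector and subject j's run-2 FC vector.  Its diagonal measures
self-similarity; derived statistics are:

* ``Iself``  — mean diagonal, ``Iothers`` — mean off-diagonal (both
  triangles, since I is asymmetric), ``Idiff = Iself - Iothers``;
* Cohen's d — (Iself - Iothers) / sqrt((s2_self + s2_others) / 2) with
  sample variances (ddof=1) over the diagonal and off-diagonal sets;
* success rate — fraction of rows whose strict maximum sits on the
  diagonal (an exact tie counts as a failure, with a warning);
* top-K accuracy — fraction of rows whose diagonal entry ranks within the
  K largest of the row (ties broken toward the lower column index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .connectivity import FCVector


class FingerprintError(ValueError):
    pass


def _check_square(I: np.ndarray) -> np.ndarray:
    I = np.asarray(I, dtype=float)
    if I.ndim != 2 or I.shape[0] != I.shape[1]:
        raise FingerprintError(f"identifiability matrix must be square, got {I.shape}")
    if I.shape[0] < 2:
        raise FingerprintError("need at least 2 subjects")
    return I


def identifiability_matrix(run1_vectors: list[FCVector],
                           run2_vectors: list[FCVector]) -> np.ndarray:
    """Correlate every run-1 FC vector (rows) with every run-2 vector (columns)."""
    if len(run1_vectors) != len(run2_vectors):
        raise FingerprintError(
            f"run counts differ: {len(run1_vectors)} vs {len(run2_vectors)}"
        )
    if len(run1_vectors) < 2:
        raise FingerprintError("need at least 2 subjects")
    ref = run1_vectors[0].edge_index
    for vec in run1_vectors[1:] + run2_vectors:
        if vec.edge_index != ref:
            bad = next(
                (a, b) for a, b in zip(vec.edge_index, ref) if a != b
            ) if len(vec.edge_index) == len(ref) else (len(vec.edge_index), len(ref))
            raise FingerprintError(f"mismatched edge sets (first discrepancy: {bad})")
    X = np.array([v.values for v in run1_vectors], dtype=float)
    Y = np.array([v.values for v in run2_vectors], dtype=float)

    def _standardize(A: np.ndarray) -> np.ndarray:
        A = A - A.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(A, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise FingerprintError("constant FC vector has undefined correlation")
        return A / norms

    return _standardize(X) @ _standardize(Y).T


def idiff(I: np.ndarray) -> tuple[float, float, float]:
    """(Iself, Iothers, Idiff) of an identifiability matrix."""
    I = _check_square(I)
    off = ~np.eye(I.shape[0], dtype=bool)
    iself = float(np.diag(I).mean())
    iothers = float(I[off].mean())
    return iself, iothers, iself - iothers


def cohens_d(I: np.ndarray) -> float:
    """Standardized self-vs-others separation (pooled SD, sample variances)."""
    I = _check_square(I)
    diag = np.diag(I)
    off = I[~np.eye(I.shape[0], dtype=bool)]
    v_self = float(np.var(diag, ddof=1))
    v_others = float(np.var(off, ddof=1))
    pooled = (v_self + v_others) / 2.0
    if pooled == 0:
        warnings.warn("zero variance in both similarity sets; Cohen's d undefined",
                      stacklevel=2)
        return float("nan")
    return float((diag.mean() - off.mean()) / np.sqrt(pooled))


def success_rate(I: np.ndarray) -> tuple[int, float]:
    """(count, unrounded percent) of rows whose strict max is the diagonal."""
    I = _check_square(I)
    ns = I.shape[0]
    count = 0
    for i in range(ns):
        row = I[i]
        m = row.max()
        if row[i] == m:
            if (row == m).sum() > 1:
                warnings.warn(
                    f"row {i}: tie at the maximum involving the diagonal; "
                    "counted as a failed identification", stacklevel=2)
            else:
                count += 1
    return count, 100.0 * count / ns


def topk_accuracy(I: np.ndarray, k_max: int = 5) -> dict[int, float]:
    """Percent of subjects whose self-match ranks within the top K, K=1..k_max."""
    I = _check_square(I)
    ns = I.shape[0]
    if not 1 <= k_max <= ns:
        raise FingerprintError(f"k_max must be in [1, {ns}], got {k_max}")
    # stable argsort on -row: ties resolved toward the lower column index
    ranks = np.empty(ns, dtype=int)
    for i in range(ns):
        order = np.argsort(-I[i], kind="stable")
        ranks[i] = int(np.flatnonzero(order == i)[0])
    return {k: float(100.0 * np.mean(ranks < k)) for k in range(1, k_max + 1)}


def chance_level(ns: int) -> float:
    """Expected top-1 accuracy (percent) under random assignment."""
    if ns < 1:
        raise FingerprintError("need at least one subject")
    return 100.0 / ns


def format_percent(value: float) -> str:
    """One-decimal percent string, e.g. 5.6%."""
    return f"{value:.1f}%"


@dataclass
class IdentifiabilityResult:
    """Identifiability matrix plus all derived fingerprint statistics."""

    I: np.ndarray
    subject_order: list[str]
    iself: float
    iothers: float
    idiff: float
    var_self: float
    var_others: float
    cohens_d: float
    success_count: int
    accuracy: float           # percent, unrounded
    topk: dict[int, float]    # K -> percent
    chance: float = field(init=False)

    def __post_init__(self) -> None:
        self.chance = chance_level(len(self.subject_order))

    @property
    def ns(self) -> int:
        return len(self.subject_order)

    def to_report(self) -> dict:
        """JSON-ready summary with full precision and rounded display strings."""
        return {
            "n_subjects": self.ns,
            "subject_order": list(self.subject_order),
            "iself": self.iself,
            "iothers": self.iothers,
            "idiff": self.idiff,
            "cohens_d": self.cohens_d,
            "success_count": self.success_count,
            "accuracy_percent": self.accuracy,
            "accuracy_display": format_percent(self.accuracy),
            "chance_percent": self.chance,
            "chance_display": format_percent(self.chance),
            "topk_percent": {str(k): v for k, v in self.topk.items()},
        }


def fingerprint(run1_vectors: list[FCVector], run2_vectors: list[FCVector],
                k_max: int = 5, symmetric: bool = False) -> IdentifiabilityResult:
    """Full fingerprint analysis of two ordered sets of FC vectors.

    ``symmetric=True`` averages the row-wise (run1 -> run2) and
    column-wise success rates; the default follows the ordered row-wise
    definition.
    """
    I = identifiability_matrix(run1_vectors, run2_vectors)
    ids = [v.subject_id for v in run1_vectors]
    iself, iothers, diff = idiff(I)
    diag = np.diag(I)
    off = I[~np.eye(I.shape[0], dtype=bool)]
    count, acc = success_rate(I)
    if symmetric:
        count_c, acc_c = success_rate(I.T)
        acc = (acc + acc_c) / 2.0
        count = count + count_c  # out of 2*Ns
    k_max = min(k_max, I.shape[0])
    return IdentifiabilityResult(
        I=I, subject_order=ids, iself=iself, iothers=iothers, idiff=diff,
        var_self=float(np.var(diag, ddof=1)), var_others=float(np.var(off, ddof=1)),
        cohens_d=cohens_d(I), success_count=count, accuracy=acc,
        topk=topk_accuracy(I, k_max),
    )


def sort_by_diagonal(result: IdentifiabilityResult) -> IdentifiabilityResult:
    """Jointly permute rows/columns so the diagonal is descending.

    All scalar statistics are invariant under this relabeling; only the
    matrix layout and subject order change.
    """
    perm = np.argsort(-np.diag(result.I), kind="stable")
    I_sorted = result.I[np.ix_(perm, perm)]
    order = [result.subject_order[p] for p in perm]
    return replace(result, I=I_sorted, subject_order=order)
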