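"""Linear removal of shared brain-spine variance and residual fingerprinting.

With simultaneously acquired brain and spinal time series sharing a time
axis, the model Y = X b + e (columns demeaned, minimum-norm least
squares, no intercept) strips from the target block everything linearly
explained by the predictor block.  Residual FC profiles then measure
identifiability of the variance a region generates on its own:
``spine_given_brain`` fingerprints spinal activity unexplained by the
brain, ``brain_given_spine`` the converse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import compute_fc, vectorize_fc
from .fingerprint import IdentifiabilityResult, fingerprint
from .parcellation import ParcelledRun
from .synthetic import SyntheticCohort

DIRECTIONS = ("spine_given_brain", "brain_given_spine")


class ResidualizationError(ValueError):
    pass


@dataclass
class RegressionResult:
    beta: np.ndarray        # n_pred x n_target
    fitted: np.ndarray      # T x n_target, includes the target column means
    residuals: np.ndarray   # T x n_target
    direction: str = ""


def fit_linear_model(Y: np.ndarray, X: np.ndarray,
                     direction: str = "") -> RegressionResult:
    """Minimum-norm least squares of demeaned Y on demeaned X.

    Decomposes exactly: Y = fitted + residuals.  Residual columns are
    orthogonal to every demeaned predictor column.  Warns when the
    predictor count reaches T (perfect-fit regime: residuals vanish).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.ndim != 2 or X.ndim != 2:
        raise ResidualizationError("Y and X must be 2-D time x ROI arrays")
    if Y.shape[0] != X.shape[0]:
        raise ResidualizationError(
            f"time axes differ: Y has T={Y.shape[0]}, X has T={X.shape[0]}")
    if Y.shape[0] < 2:
        raise ResidualizationError("need at least 2 time points")
    if X.shape[1] >= X.shape[0]:
        warnings.warn(
            f"{X.shape[1]} predictors for {X.shape[0]} time points: perfect-fit "
            "regime, residuals will be (near) zero", stacklevel=2)
    y_mean = Y.mean(axis=0, keepdims=True)
    xc = X - X.mean(axis=0, keepdims=True)
    yc = Y - y_mean
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ beta + y_mean
    residuals = Y - fitted
    return RegressionResult(beta=beta, fitted=fitted, residuals=residuals,
                            direction=direction)


def residualize_run(run: ParcelledRun, direction: str) -> ParcelledRun:
    """Residual time series of the target block of one combined run."""
    if direction not in DIRECTIONS:
        raise ResidualizationError(
            f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if not (run.labels.has_brain and run.labels.has_spine):
        raise ResidualizationError(
            f"run {run.subject_id!r} lacks a brain or spine block")
    target, predictor = (("spine", "brain") if direction == "spine_given_brain"
                         else ("brain", "spine"))
    y_run = run.block(target)
    x_run = run.block(predictor)
    res = fit_linear_model(y_run.data, x_run.data, direction=direction)
    if np.allclose(res.residuals, 0.0, atol=1e-12):
        raise ResidualizationError(
            f"all residuals vanish for subject {run.subject_id!r} run {run.run} "
            "(predictor block explains the target exactly)")
    return ParcelledRun(y_run.subject_id, y_run.run, res.residuals, y_run.labels)


def residual_fingerprint(cohort: SyntheticCohort | list[tuple[ParcelledRun, ParcelledRun]],
                         direction: str, k_max: int = 5) -> IdentifiabilityResult:
    """Fingerprint the residual FC profiles of a two-run cohort."""
    pairs = cohort.runs if isinstance(cohort, SyntheticCohort) else cohort
    vecs1, vecs2 = [], []
    for r1, r2 in pairs:
        vecs1.append(vectorize_fc(compute_fc(residualize_run(r1, direction))))
        vecs2.append(vectorize_fc(compute_fc(residualize_run(r2, direction))))
    return fingerprint(vecs1, vecs2, k_max=k_max)
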