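"""Synthetic two-run cohorts with controllable subject distinctiveness.

The generator emulates the statistical skeleton of a test-retest cohort:
each subject owns a latent-factor covariance that is stable across runs
(the fingerprint), each run perturbs it (session noise), and observations
are multivariate-normal time series.  Per subject i the factor loadings
are ``A_i = A_group + lambda_subject * B_i`` (entries standard normal),
giving the positive-definite covariance ``C_i = A_i A_i' + sigma_obs^2 I``.
Per run, ``C_i`` is perturbed by a symmetric random matrix scaled by
``sigma_run`` and projected back to positive definite by eigenvalue
flooring.  ``lambda_subject`` therefore moves identifiability up and
``sigma_run`` moves it down.

For a combined brain+spine parcellation with ``coupling`` c > 0, spinal
series are a mixture ``sqrt(1-c) * intrinsic + sqrt(c) * brain-driven``,
where the brain-driven part is the brain series passed through a
subject-specific mixing matrix.  Regressing brain signals out of spinal
signals then removes an identifiable component, reproducing the direction
of the brain->spine residualization effect.

All randomness flows from a single integer seed through per-(subject,
run, purpose) counter-keyed substreams, so adding subjects to a spec does
not alter the data of existing subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .parcellation import ParcelledRun, Parcellation

EIG_FLOOR_FRACTION = 1e-6  # floor eigenvalues at this fraction of the leading one

# substream purpose tags
_GROUP_LOADINGS = 0
_SUBJECT_LOADINGS = 1
_RUN_PERTURBATION = 2
_RUN_SAMPLING = 3
_COUPLING_GROUP = 4
_COUPLING_SUBJECT = 5


class CohortSpecError(ValueError):
    pass


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic two-run cohort.

    Defaults mirror a single-session spinal study: 15 subjects, C4-C6
    parcellation (42 ROIs), 300 time points per run, moderate subject
    distinctiveness and run noise.
    """

    n_subjects: int
    parcellation: Parcellation
    T: int = 300
    k_factors: int = 5
    lambda_subject: float = 0.2
    sigma_run: float = 3.0
    sigma_obs: float = 1.0
    coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise CohortSpecError("need at least one subject")
        if self.T < 3:
            raise CohortSpecError("need at least 3 time points")
        if self.k_factors < 1:
            raise CohortSpecError("need at least one latent factor")
        for name in ("lambda_subject", "sigma_run"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise CohortSpecError(f"{name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.sigma_obs) or self.sigma_obs <= 0:
            raise CohortSpecError(f"sigma_obs must be > 0, got {self.sigma_obs}")
        if not 0 <= self.coupling <= 1:
            raise CohortSpecError(f"coupling must lie in [0, 1], got {self.coupling}")
        if self.coupling > 0 and not (
            self.parcellation.has_brain and self.parcellation.has_spine
        ):
            raise CohortSpecError(
                "coupling > 0 requires a parcellation with brain and spine blocks"
            )
        if self.T <= self.parcellation.N:
            warnings.warn(
                f"T={self.T} <= N={self.parcellation.N}: FC estimates will be "
                "rank-deficient and noisy", stacklevel=2)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "roi_names": self.parcellation.names,
            "T": self.T,
            "k_factors": self.k_factors,
            "lambda_subject": self.lambda_subject,
            "sigma_run": self.sigma_run,
            "sigma_obs": self.sigma_obs,
            "coupling": self.coupling,
            "seed": self.seed,
        }


def _block_covariances(spec: CohortSpec, n: int, block_tag: int) -> list[np.ndarray]:
    """Factor-model covariances C_i = A_i A_i' + sigma_obs^2 I for one block."""
    a_group = _rng(spec.seed, _GROUP_LOADINGS, block_tag).standard_normal(
        (n, spec.k_factors))
    covs = []
    for i in range(spec.n_subjects):
        b_i = _rng(spec.seed, _SUBJECT_LOADINGS, block_tag, i).standard_normal(
            (n, spec.k_factors))
        a_i = a_group + spec.lambda_subject * b_i
        covs.append(a_i @ a_i.T + spec.sigma_obs**2 * np.eye(n))
    return covs


def generate_subject_covariances(spec: CohortSpec) -> list[np.ndarray]:
    """Per-subject N x N target covariances (positive definite by construction).

    For a combined parcellation the exact joint covariance of the coupled
    brain+spine process is assembled (brain block, spinal block, and their
    cross-covariance induced by the mixing matrix).
    """
    parc = spec.parcellation
    if not (parc.has_brain and parc.has_spine):
        return _block_covariances(spec, parc.N, 0)

    n_br = int(parc.brain_mask.sum())
    n_sc = int(parc.spinal_mask.sum())
    cov_br = _block_covariances(spec, n_br, 0)
    cov_sc = _block_covariances(spec, n_sc, 1)
    c = spec.coupling
    out = []
    for i in range(spec.n_subjects):
        w = _mixing_matrix(spec, i, n_br, n_sc)
        # spine_obs = sqrt(1-c) * intrinsic + sqrt(c) * brain @ w
        cov_ss = (1 - c) * cov_sc[i] + c * w.T @ cov_br[i] @ w
        cov_bs = np.sqrt(c) * cov_br[i] @ w
        out.append(_assemble_joint(parc, cov_br[i], cov_ss, cov_bs))
    return out


def _assemble_joint(parc: Parcellation, cov_bb: np.ndarray, cov_ss: np.ndarray,
                    cov_bs: np.ndarray) -> np.ndarray:
    n = parc.N
    bi = np.flatnonzero(parc.brain_mask)
    si = np.flatnonzero(parc.spinal_mask)
    cov = np.empty((n, n))
    cov[np.ix_(bi, bi)] = cov_bb
    cov[np.ix_(si, si)] = cov_ss
    cov[np.ix_(bi, si)] = cov_bs
    cov[np.ix_(si, bi)] = cov_bs.T
    return cov


def _mixing_matrix(spec: CohortSpec, subject: int, n_br: int, n_sc: int) -> np.ndarray:
    """Subject-specific brain->spine mixing, normalized to preserve variance."""
    w_group = _rng(spec.seed, _COUPLING_GROUP).standard_normal((n_br, n_sc))
    w_dev = _rng(spec.seed, _COUPLING_SUBJECT, subject).standard_normal((n_br, n_sc))
    w = w_group + spec.lambda_subject * w_dev
    return w / np.sqrt(n_br * (1 + spec.lambda_subject**2))


def perturb_covariance(cov: np.ndarray, sigma_run: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Symmetric random perturbation followed by eigenvalue flooring."""
    n = cov.shape[0]
    if sigma_run == 0:
        return cov.copy()
    s = rng.standard_normal((n, n))
    pert = cov + sigma_run * (s + s.T) / 2.0
    vals, vecs = np.linalg.eigh(pert)
    floor = EIG_FLOOR_FRACTION * vals[-1]
    if floor <= 0:  # pathological all-nonpositive spectrum
        floor = EIG_FLOOR_FRACTION
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def sample_run_timeseries(cov: np.ndarray, T: int, sigma_run: float,
                          rng_perturb: np.random.Generator,
                          rng_sample: np.random.Generator) -> np.ndarray:
    """Draw T rows of a zero-mean Gaussian with run-perturbed covariance."""
    run_cov = perturb_covariance(np.asarray(cov, float), sigma_run, rng_perturb)
    vals, vecs = np.linalg.eigh(run_cov)
    vals = np.maximum(vals, 0.0)
    root = vecs * np.sqrt(vals)
    z = rng_sample.standard_normal((T, run_cov.shape[0]))
    return z @ root.T


@dataclass
class SyntheticCohort:
    """Generated two-run cohort plus the ground-truth covariances."""

    spec: CohortSpec
    runs: list[tuple[ParcelledRun, ParcelledRun]]
    true_covariances: list[np.ndarray] = field(repr=False)

    @property
    def subject_ids(self) -> list[str]:
        return [pair[0].subject_id for pair in self.runs]

    def run_list(self, run: int) -> list[ParcelledRun]:
        if run not in (1, 2):
            raise CohortSpecError("run must be 1 or 2")
        return [pair[run - 1] for pair in self.runs]


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full cohort: n_subjects x 2 parcelled runs."""
    parc = spec.parcellation
    combined = parc.has_brain and parc.has_spine
    if combined:
        n_br = int(parc.brain_mask.sum())
        n_sc = int(parc.spinal_mask.sum())
        cov_br = _block_covariances(spec, n_br, 0)
        cov_sc = _block_covariances(spec, n_sc, 1)
    else:
        covs = _block_covariances(spec, parc.N, 0)
    true_covs = generate_subject_covariances(spec)

    runs = []
    c = spec.coupling
    for i in range(spec.n_subjects):
        sid = f"sub-{i + 1:02d}"
        pair = []
        for r in (1, 2):
            if combined:
                x_br = sample_run_timeseries(
                    cov_br[i], spec.T, spec.sigma_run,
                    _rng(spec.seed, _RUN_PERTURBATION, i, r, 0),
                    _rng(spec.seed, _RUN_SAMPLING, i, r, 0))
                e_sc = sample_run_timeseries(
                    cov_sc[i], spec.T, spec.sigma_run,
                    _rng(spec.seed, _RUN_PERTURBATION, i, r, 1),
                    _rng(spec.seed, _RUN_SAMPLING, i, r, 1))
                w = _mixing_matrix(spec, i, n_br, n_sc)
                x_sc = np.sqrt(1 - c) * e_sc + np.sqrt(c) * (x_br @ w)
                data = np.empty((spec.T, parc.N))
                data[:, parc.brain_mask] = x_br
                data[:, parc.spinal_mask] = x_sc
            else:
                data = sample_run_timeseries(
                    covs[i], spec.T, spec.sigma_run,
                    _rng(spec.seed, _RUN_PERTURBATION, i, r, 0),
                    _rng(spec.seed, _RUN_SAMPLING, i, r, 0))
            pair.append(ParcelledRun(sid, r, data, parc))
        runs.append((pair[0], pair[1]))
    return SyntheticCohort(spec=spec, runs=runs, true_covariances=true_covs)
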