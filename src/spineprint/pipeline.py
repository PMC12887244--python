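"""End-to-end orchestration: cohort -> FC -> fingerprint -> ICC -> PCA -> residuals.

A pipeline run is fully determined by its config (including the seed):
the same config produces byte-identical reports.  Outputs are a JSON
report with full-precision statistics plus display strings rounded the
way fingerprint studies report them, TSV matrices, and a small run log.
"""

from __future__ import annotations

import glob as _glob
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .connectivity import compute_fc, vectorize_fc, FCVector
from .fingerprint import (
    IdentifiabilityResult, fingerprint, format_percent, sort_by_diagonal,
)
from .io import load_run_pairs, write_cohort, write_matrix_tsv
from .parcellation import (
    ParcelledRun, build_brain_parcellation, build_spinal_parcellation,
)
from .pca import idiff_sweep
from .reliability import (
    average_level_blocks, icc_matrix, nodal_strength, threshold_percentile,
)
from .residualization import DIRECTIONS, residual_fingerprint
from .synthetic import CohortSpec, generate_cohort

log = logging.getLogger("spineprint")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; round-trips losslessly through YAML."""

    mode: str = "simulate"                  # simulate | tsv
    out_dir: str = "spineprint_out"
    seed: int = 0
    log_level: str = "INFO"
    # tsv mode
    run1_glob: str = ""
    run2_glob: str = ""
    # simulate mode (cohort spec)
    n_subjects: int = 15
    levels: list[str] = field(default_factory=lambda: ["C4", "C5", "C6"])
    include_brain: bool = False
    T: int = 300
    k_factors: int = 5
    lambda_subject: float = 0.2
    sigma_run: float = 3.0
    sigma_obs: float = 1.0
    coupling: float = 0.0
    # analysis toggles
    topk_max: int = 5
    sort_matrix: bool = True
    run_pca_sweep: bool = True
    icc_pct: float = 95.0
    nodal_mode: str = "sum"
    residual_direction: str = "both"        # both | spine_given_brain | ... | none

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "tsv"):
            raise PipelineError(f"unknown input mode {self.mode!r}")
        if self.mode == "tsv" and not (self.run1_glob and self.run2_glob):
            raise PipelineError("tsv mode requires run1_glob and run2_glob")
        if self.residual_direction not in DIRECTIONS + ("both", "none"):
            raise PipelineError(
                f"residual_direction must be 'both', 'none' or one of {DIRECTIONS}")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise PipelineError(f"config file {path} is not a mapping")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def cohort_spec(self) -> CohortSpec:
        parc = build_spinal_parcellation(self.levels)
        if self.include_brain:
            parc = parc + build_brain_parcellation()
        return CohortSpec(
            n_subjects=self.n_subjects, parcellation=parc, T=self.T,
            k_factors=self.k_factors, lambda_subject=self.lambda_subject,
            sigma_run=self.sigma_run, sigma_obs=self.sigma_obs,
            coupling=self.coupling, seed=self.seed)


def cohort_vectors(pairs: list[tuple[ParcelledRun, ParcelledRun]],
                   block: str | None = None
                   ) -> tuple[list[FCVector], list[FCVector]]:
    """FC vectors of both runs, optionally restricted to one block."""
    v1, v2 = [], []
    for r1, r2 in pairs:
        if block is not None:
            r1, r2 = r1.block(block), r2.block(block)
        v1.append(vectorize_fc(compute_fc(r1)))
        v2.append(vectorize_fc(compute_fc(r2)))
    return v1, v2


def _fingerprint_section(result: IdentifiabilityResult) -> dict:
    return result.to_report()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and persist the report bundle under out_dir."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        if config.mode == "simulate":
            spec = config.cohort_spec()
            cohort = generate_cohort(spec)
            write_cohort(cohort, out / "timeseries")
            pairs = cohort.runs
            log.info("simulated cohort: %d subjects, N=%d, T=%d",
                     spec.n_subjects, spec.parcellation.N, spec.T)
        else:
            pairs = load_run_pairs(sorted(_glob.glob(config.run1_glob)),
                                   sorted(_glob.glob(config.run2_glob)))
            log.info("loaded %d subject pairs from TSV", len(pairs))

        parc = pairs[0][0].labels
        combined = parc.has_brain and parc.has_spine
        report: dict = {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "config": asdict(config),
            "n_subjects": len(pairs),
            "n_rois": parc.N,
            "profiles": {},
        }

        profiles = {"full": None} if not combined else {
            "full": None, "spine": "spine", "brain": "brain"}
        primary_key = "spine" if combined else "full"
        primary_vectors = None
        for key, block in profiles.items():
            stage = f"fingerprint[{key}]"
            v1, v2 = cohort_vectors(pairs, block)
            res = fingerprint(v1, v2, k_max=min(config.topk_max, len(pairs)))
            if config.sort_matrix:
                res = sort_by_diagonal(res)
            report["profiles"][key] = _fingerprint_section(res)
            write_matrix_tsv(res.I, res.subject_order,
                             out / f"identifiability_{key}.tsv")
            if key == primary_key:
                primary_vectors = (v1, v2)
        assert primary_vectors is not None
        v1, v2 = primary_vectors

        stage = "icc"
        icc = icc_matrix(v1, v2)
        thr, filtered = threshold_percentile(icc.values, config.icc_pct)
        strength = nodal_strength(filtered, mode=config.nodal_mode)
        roi_names = v1[0].labels.names
        write_matrix_tsv(np.nan_to_num(icc.values, nan=0.0), roi_names,
                         out / "icc_matrix.tsv")
        write_matrix_tsv(filtered, roi_names, out / "icc_thresholded.tsv")
        icc_section = {
            "threshold_percentile": config.icc_pct,
            "threshold_value": thr,
            "max_icc": float(np.nanmax(icc.values)),
            "nodal_strength": dict(zip(roi_names, strength.tolist())),
        }
        if v1[0].labels.has_spine and not v1[0].labels.has_brain:
            level_avg = average_level_blocks([icc])
            write_matrix_tsv(np.nan_to_num(level_avg, nan=0.0),
                             [lab.name.split("_", 1)[1]
                              for lab in v1[0].labels.labels[:level_avg.shape[0]]],
                             out / "icc_level_average.tsv")
            icc_section["level_average_max"] = float(np.nanmax(level_avg))
        report["icc"] = icc_section

        if config.run_pca_sweep:
            stage = "pca_sweep"
            sweep = idiff_sweep(v1, v2)
            report["pca_sweep"] = {
                "m_values": sweep.m_values,
                "idiff_by_m": sweep.idiff_by_m,
                "m_star": sweep.m_star,
                "idiff_star": sweep.idiff_star,
                "idiff_full": sweep.idiff_full,
            }

        if combined and config.residual_direction != "none":
            directions = (DIRECTIONS if config.residual_direction == "both"
                          else (config.residual_direction,))
            report["residual"] = {}
            for d in directions:
                stage = f"residualize[{d}]"
                res = residual_fingerprint(list(pairs), d,
                                           k_max=min(config.topk_max, len(pairs)))
                if config.sort_matrix:
                    res = sort_by_diagonal(res)
                report["residual"][d] = _fingerprint_section(res)
                write_matrix_tsv(res.I, res.subject_order,
                                 out / f"identifiability_residual_{d}.tsv")
    except Exception as exc:
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text(
        f"spineprint {__version__}\nconfig_hash {config.config_hash()}\n"
        f"stages completed through {stage}\n")
    log.info("report written to %s", out / "report.json")
    return report


def chance_display(ns: int) -> str:
    """One-decimal chance-level string for a cohort of ns subjects."""
    return format_percent(100.0 / ns)
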