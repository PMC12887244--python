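"""Readers and writers for the package's plain-text interchange formats.

Time series travel as TSV (header = ROI names, one row per time point,
file name ``<subject>_run-<r>_timeseries.tsv``); matrices as TSV with ROI
names on both axes; cohorts carry a JSON manifest of their generative
spec.  Voxel data enter through NIfTI (4-D functional + 3-D integer
label volume + TSV label lookup).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import FCVector
from .parcellation import (
    ROILabel, Parcellation, ParcellationError, ParcelledRun, VoxelRun,
    REGION_TISSUE, SIDES, SPINAL_LEVELS,
)
from .synthetic import SyntheticCohort

_RUN_FILE_RE = re.compile(r"(?P<subject>.+)_run-(?P<run>\d+)_timeseries(_resid)?\.tsv$")

_SPINAL_NAME_RE = re.compile(
    rf"^(?P<level>{'|'.join(SPINAL_LEVELS)})_(?P<region>[a-z]+)_(?P<side>[LR])$")


class IOError_(ValueError):
    pass


def label_from_name(name: str) -> ROILabel:
    """Reconstruct an ROI label from its canonical name.

    Names matching ``<level>_<region>_<side>`` become spinal labels; any
    other name is treated as a brain ROI (network tag recovered from
    ``BR_<net>_<idx>`` names when present).
    """
    m = _SPINAL_NAME_RE.match(name)
    if m and m.group("region") in REGION_TISSUE:
        region = m.group("region")
        return ROILabel(name=name, level=m.group("level"),
                        tissue=REGION_TISSUE[region], region=region,
                        side=m.group("side"))
    parts = name.split("_")
    region = parts[1] if name.startswith("BR_") and len(parts) == 3 else "unknown"
    return ROILabel(name=name, level="brain", tissue="brain", region=region, side="NA")


def parcellation_from_names(names: list[str]) -> Parcellation:
    return Parcellation(tuple(label_from_name(n) for n in names))


def timeseries_filename(subject_id: str, run: int, suffix: str = "") -> str:
    return f"{subject_id}_run-{run}_timeseries{suffix}.tsv"


def write_timeseries_tsv(run: ParcelledRun, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(run.data, columns=run.labels.names)
    # default float formatting is the shortest repr, which round-trips exactly
    df.to_csv(path, sep="\t", index=False)
    return path


def read_timeseries_tsv(path: str | Path, subject_id: str | None = None,
                        run: int | None = None) -> ParcelledRun:
    path = Path(path)
    if not path.exists():
        raise IOError_(f"no such time-series file: {path}")
    if path.stat().st_size == 0:
        raise IOError_(f"empty time-series file: {path}")
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        dup = next(n for n in header if header.count(n) > 1)
        raise IOError_(f"duplicate ROI name {dup!r} in {path}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=float,
                         float_precision="round_trip")
    except ValueError as exc:
        raise IOError_(f"malformed time-series file {path}: {exc}") from exc
    if df.shape[0] == 0:
        raise IOError_(f"time-series file {path} has a header but no data rows")
    names = [str(c) for c in df.columns]
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise IOError_(f"non-numeric or missing cells in {path}")
    m = _RUN_FILE_RE.match(path.name)
    if subject_id is None:
        subject_id = m.group("subject") if m else path.stem
    if run is None:
        run = int(m.group("run")) if m else 1
    try:
        return ParcelledRun(subject_id, run, values, parcellation_from_names(names))
    except ParcellationError as exc:
        raise IOError_(f"invalid time series in {path}: {exc}") from exc


def write_matrix_tsv(values: np.ndarray, names: list[str], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(np.asarray(values, float), index=names, columns=names)
    df.to_csv(path, sep="\t")
    return path


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_vector_tsv(vec: FCVector, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"edge": vec.edge_names(), "value": vec.values}).to_csv(
        path, sep="\t", index=False, float_format="%.17g")
    return path


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write every run as TSV plus a JSON manifest of the generating spec."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for r1, r2 in cohort.runs:
        for r in (r1, r2):
            write_timeseries_tsv(r, out_dir / timeseries_filename(r.subject_id, r.run))
    manifest = out_dir / "cohort_manifest.json"
    manifest.write_text(json.dumps(cohort.spec.to_dict(), indent=2) + "\n")
    return out_dir


def load_run_pairs(run1_paths: list[str | Path], run2_paths: list[str | Path]
                   ) -> list[tuple[ParcelledRun, ParcelledRun]]:
    """Pair run-1 and run-2 time-series files by subject id."""
    runs1 = {r.subject_id: r for r in (read_timeseries_tsv(p) for p in sorted(map(str, run1_paths)))}
    runs2 = {r.subject_id: r for r in (read_timeseries_tsv(p) for p in sorted(map(str, run2_paths)))}
    if set(runs1) != set(runs2):
        missing = set(runs1) ^ set(runs2)
        raise IOError_(f"subjects present in only one run: {sorted(missing)}")
    return [(runs1[s], runs2[s]) for s in sorted(runs1)]


def read_label_lookup_tsv(path: str | Path) -> dict[int, ROILabel]:
    """Lookup table mapping label volume integers to ROI labels."""
    df = pd.read_csv(path, sep="\t")
    required = {"label_int", "name", "level", "tissue", "region", "side"}
    if not required.issubset(df.columns):
        raise IOError_(f"lookup file {path} must have columns {sorted(required)}")
    lookup = {}
    for row in df.itertuples(index=False):
        lookup[int(row.label_int)] = ROILabel(
            name=str(row.name), level=str(row.level), tissue=str(row.tissue),
            region=str(row.region), side=str(row.side))
    return lookup


def load_voxel_run(func_path: str | Path, roi_path: str | Path,
                   lookup_path: str | Path, subject_id: str = "unknown",
                   run: int = 1) -> VoxelRun:
    """Load a 4-D NIfTI functional image with its ROI label volume."""
    import nibabel as nib

    img = nib.load(str(func_path))
    roi = nib.load(str(roi_path))
    lookup = read_label_lookup_tsv(lookup_path)
    vox = VoxelRun(image=np.asarray(img.dataobj, dtype=float),
                   roi_volume=np.asarray(roi.dataobj).astype(int),
                   lookup=lookup, subject_id=subject_id, run=run)
    for label_int, lab in lookup.items():
        if not (vox.roi_volume == label_int).any():
            raise IOError_(f"ROI {lab.name!r} (label {label_int}) has no voxels "
                           f"in {roi_path}")
    return vox
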