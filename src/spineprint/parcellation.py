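"""ROI label schemes and parcel time-series extraction.

The spinal cross-section is divided into 14 bilateral regions: three
gray-matter regions (dorsal horn ``dh``, intermediate zone ``iz``, ventral
horn ``vh``) and four white-matter regions (corticospinal tract ``cst``,
fasciculus cuneatus ``fc``, fasciculus gracilis ``fg``, spinal lemniscus
``sl``), each on the left and right.  A spinal parcellation is the
concatenation of this scheme over a contiguous range of cervical levels
(C2..C8), so its size is always ``14 * n_levels`` (42 for C4-C6, 70 for
C4-C8, 98 for C2-C8).  An optional brain block of 119 ROIs (100 cortical
split over seven canonical resting-state networks plus 19 subcortical
areas) can be appended for combined brain+spine analyses.

Voxel data are reduced to parcel time series with a robust mean: at each
time point, voxels of an ROI whose values fall outside the [5th, 95th]
percentile band are discarded before averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

SPINAL_LEVELS = ("C2", "C3", "C4", "C5", "C6", "C7", "C8")

# canonical cross-section order: GM dorsal->ventral, then WM; L before R
GM_REGIONS = ("dh", "iz", "vh")
WM_REGIONS = ("cst", "fc", "fg", "sl")
SIDES = ("L", "R")

REGION_TISSUE = {r: "GM" for r in GM_REGIONS} | {r: "WM" for r in WM_REGIONS}

ROIS_PER_LEVEL = len(SIDES) * (len(GM_REGIONS) + len(WM_REGIONS))  # 14

BRAIN_NETWORKS = ("VIS", "SM", "DA", "VA", "LIM", "FP", "DMN")
N_BRAIN_CORTICAL = 100
N_BRAIN_SUBCORTICAL = 19
N_BRAIN = N_BRAIN_CORTICAL + N_BRAIN_SUBCORTICAL  # 119


class ParcellationError(ValueError):
    """Raised for invalid ROI schemes or malformed parcel inputs."""


@dataclass(frozen=True)
class ROILabel:
    """A single region of interest.

    ``level`` is a spinal level tag (C2..C8) or ``"brain"``; ``tissue`` is
    GM/WM for spinal ROIs and ``"brain"`` otherwise; ``region`` is the
    cross-sectional region code or a brain-network tag; ``side`` is L/R
    for bilateral spinal ROIs and ``"NA"`` where laterality does not apply.
    """

    name: str
    level: str
    tissue: str
    region: str
    side: str

    def __post_init__(self) -> None:
        if self.level in SPINAL_LEVELS:
            if self.side not in SIDES:
                raise ParcellationError(
                    f"spinal ROI {self.name!r} must have side L or R, got {self.side!r}"
                )
            expected = REGION_TISSUE.get(self.region)
            if expected is None:
                raise ParcellationError(
                    f"unknown spinal region {self.region!r} for ROI {self.name!r}"
                )
            if expected != self.tissue:
                raise ParcellationError(
                    f"region {self.region!r} belongs to {expected}, not {self.tissue!r}"
                )
        elif self.level != "brain":
            raise ParcellationError(f"unknown level tag {self.level!r}")

    @property
    def is_spinal(self) -> bool:
        return self.level in SPINAL_LEVELS


@dataclass(frozen=True)
class Parcellation:
    """An ordered, duplicate-free collection of ROI labels."""

    labels: tuple[ROILabel, ...]

    def __post_init__(self) -> None:
        names = [lab.name for lab in self.labels]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ParcellationError(f"duplicate ROI name {dup!r}")

    @property
    def N(self) -> int:
        return len(self.labels)

    @property
    def names(self) -> list[str]:
        return [lab.name for lab in self.labels]

    @property
    def levels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab.is_spinal and lab.level not in seen:
                seen.append(lab.level)
        return seen

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def spinal_mask(self) -> np.ndarray:
        return np.array([lab.is_spinal for lab in self.labels])

    @property
    def brain_mask(self) -> np.ndarray:
        return ~self.spinal_mask

    @property
    def has_brain(self) -> bool:
        return bool(self.brain_mask.any())

    @property
    def has_spine(self) -> bool:
        return bool(self.spinal_mask.any())

    def level_indices(self, level: str) -> np.ndarray:
        """Column indices of the ROIs belonging to one spinal level."""
        idx = np.array([i for i, lab in enumerate(self.labels) if lab.level == level])
        if idx.size == 0:
            raise ParcellationError(f"level {level!r} not present in parcellation")
        return idx

    def subset(self, mask: np.ndarray) -> "Parcellation":
        return Parcellation(tuple(lab for lab, m in zip(self.labels, mask) if m))

    def __add__(self, other: "Parcellation") -> "Parcellation":
        return Parcellation(self.labels + other.labels)


def build_spinal_parcellation(levels: list[str]) -> Parcellation:
    """Canonical spinal parcellation for an ordered list of cervical levels.

    Per level the cross-section order is fixed: gray matter dh, iz, vh then
    white matter cst, fc, fg, sl, each left before right — 14 ROIs/level.
    """
    if not levels:
        raise ParcellationError("level list must be non-empty")
    if len(set(levels)) != len(levels):
        raise ParcellationError(f"duplicate levels in {levels}")
    for lv in levels:
        if lv not in SPINAL_LEVELS:
            raise ParcellationError(
                f"unknown spinal level {lv!r}; expected one of {SPINAL_LEVELS}"
            )
    labels = []
    for lv in levels:
        for region in GM_REGIONS + WM_REGIONS:
            for side in SIDES:
                labels.append(
                    ROILabel(
                        name=f"{lv}_{region}_{side}",
                        level=lv,
                        tissue=REGION_TISSUE[region],
                        region=region,
                        side=side,
                    )
                )
    return Parcellation(tuple(labels))


def build_brain_parcellation(n_cortical: int = N_BRAIN_CORTICAL,
                             n_subcortical: int = N_BRAIN_SUBCORTICAL) -> Parcellation:
    """Brain block: cortical ROIs spread over seven networks plus subcortex."""
    labels = []
    for i in range(n_cortical):
        net = BRAIN_NETWORKS[i * len(BRAIN_NETWORKS) // n_cortical]
        labels.append(
            ROILabel(name=f"BR_{net}_{i + 1:03d}", level="brain",
                     tissue="brain", region=net, side="NA")
        )
    for i in range(n_subcortical):
        labels.append(
            ROILabel(name=f"BR_SUB_{i + 1:03d}", level="brain",
                     tissue="brain", region="SUB", side="NA")
        )
    return Parcellation(tuple(labels))


@dataclass
class ParcelledRun:
    """One subject/run table of parcel time series (time x ROI)."""

    subject_id: str
    run: int
    data: np.ndarray
    labels: Parcellation

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParcellationError("data must be a 2-D time x ROI array")
        if self.data.shape[1] != self.labels.N:
            raise ParcellationError(
                f"data has {self.data.shape[1]} columns but parcellation "
                f"defines {self.labels.N} ROIs"
            )
        if self.data.shape[0] < 3:
            raise ParcellationError("need at least 3 time points")
        if not np.all(np.isfinite(self.data)):
            raise ParcellationError("non-finite values in time series")

    @property
    def T(self) -> int:
        return self.data.shape[0]

    def block(self, which: str) -> "ParcelledRun":
        """Extract the ``"spine"`` or ``"brain"`` sub-run."""
        mask = self.labels.spinal_mask if which == "spine" else self.labels.brain_mask
        if not mask.any():
            raise ParcellationError(f"run has no {which} block")
        return ParcelledRun(self.subject_id, self.run,
                            self.data[:, mask], self.labels.subset(mask))


@dataclass
class VoxelRun:
    """A 4-D functional image plus an integer ROI label volume."""

    image: np.ndarray          # X x Y x Z x T
    roi_volume: np.ndarray     # X x Y x Z integer labels, 0 = background
    lookup: dict[int, ROILabel] = field(default_factory=dict)
    subject_id: str = "unknown"
    run: int = 1

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.roi_volume = np.asarray(self.roi_volume)
        if self.image.ndim != 4:
            raise ParcellationError("image must be 4-D (X, Y, Z, T)")
        if self.roi_volume.shape != self.image.shape[:3]:
            raise ParcellationError("roi_volume shape must match image spatial shape")


def robust_parcel_mean(voxrun: VoxelRun, lower_pct: float = 5.0,
                       upper_pct: float = 95.0) -> ParcelledRun:
    """Percentile-trimmed parcel averaging.

    For each ROI and time point, voxel values outside the
    ``[lower_pct, upper_pct]`` percentile band (linear-interpolation
    percentiles over that ROI's voxels at that time point) are discarded
    and the rest averaged.  If trimming would discard everything (e.g. a
    two-voxel ROI), the untrimmed mean is used instead.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ParcellationError("need 0 <= lower_pct < upper_pct <= 100")
    items = sorted(voxrun.lookup.items())
    if not items:
        raise ParcellationError("empty ROI lookup")
    T = voxrun.image.shape[3]
    series = np.empty((T, len(items)))
    for j, (label_int, roi) in enumerate(items):
        mask = voxrun.roi_volume == label_int
        if not mask.any():
            raise ParcellationError(f"ROI {roi.name!r} (label {label_int}) has no voxels")
        vox = voxrun.image[mask, :]  # n_voxels x T
        lo = np.percentile(vox, lower_pct, axis=0)
        hi = np.percentile(vox, upper_pct, axis=0)
        keep = (vox >= lo) & (vox <= hi)
        n_keep = keep.sum(axis=0)
        sums = np.where(keep, vox, 0.0).sum(axis=0)
        trimmed = np.divide(sums, n_keep, out=np.zeros(T), where=n_keep > 0)
        series[:, j] = np.where(n_keep > 0, trimmed, vox.mean(axis=0))
    parc = Parcellation(tuple(roi for _, roi in items))
    return ParcelledRun(voxrun.subject_id, voxrun.run, series, parc)


def compute_tsnr(voxrun: VoxelRun) -> np.ndarray:
    """Voxelwise temporal SNR: temporal mean / temporal SD (ddof=0).

    Zero-variance voxels yield NaN rather than raising.
    """
    if voxrun.image.shape[3] < 2:
        raise ParcellationError("tSNR needs at least 2 time points")
    mean = voxrun.image.mean(axis=3)
    std = voxrun.image.std(axis=3, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(std > 0, mean / std, np.nan)
    if np.isnan(tsnr).any():
        warnings.warn("zero-variance voxels produced undefined tSNR", stacklevel=2)
    return tsnr
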