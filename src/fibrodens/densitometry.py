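"""Whole-lung CT densitometry.

The fibrosis readouts: cumulative HU density curves (percent of lung volume
at or above each threshold), V_T — in particular V(-200), the percent of
lung at or above -200 HU used as the extent-of-fibrosis marker — and HU
percentiles, in particular the median HU50.  As fibrosis consolidates
tissue, the HU histogram shifts right: HU50 rises from ~ -500 toward soft
tissue and V(-200) climbs from a few percent toward 100%.

Percent-volume values are count-based: all voxels of one scan share one
physical volume, so voxel counting and physical volume integration agree
exactly under uniform spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import LungMask, VoxelVolume, check_same_grid

#: The fibrosis threshold: V(-200) is always reported.
FIBROSIS_THRESHOLD_HU = -200.0

#: Default threshold grid for density curves (HU).
DEFAULT_CURVE_GRID = tuple(float(t) for t in range(-1000, 201, 10))


class EmptyMaskError(ValueError):
    """Raised when a requested label selects no voxels."""


@dataclass
class HuSample:
    """HU values of the masked voxels of one lung, with voxel geometry."""

    values: np.ndarray
    voxel_volume_mm3: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size == 0:
            raise EmptyMaskError("HU sample must contain at least one voxel")
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel_volume_mm3 must be positive")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def total_volume_mm3(self) -> float:
        return self.n * self.voxel_volume_mm3


@dataclass
class DensityCurve:
    """Percent of lung volume at or above each HU threshold.

    Non-increasing over ascending thresholds; 100% at any threshold at or
    below the sample minimum.
    """

    thresholds: np.ndarray
    percent_at_or_above: np.ndarray


@dataclass
class DensitometrySummary:
    """Per-lung densitometric readout: V_T map, HU percentiles, volume."""

    v_map: dict[float, float]
    percentiles: dict[float, float]
    lung_volume_mm3: float
    n_voxels: int

    @property
    def v200(self) -> float:
        """V(-200): percent of lung volume at or above -200 HU."""
        return self.v_map[FIBROSIS_THRESHOLD_HU]

    @property
    def hu50(self) -> float:
        """HU50: the median Hounsfield unit of the lung."""
        return self.percentiles[50.0]


def extract_hu(volume: VoxelVolume, mask: LungMask, label: int) -> HuSample:
    """Extract the HU values of exactly the voxels carrying ``label``.

    Raises
    ------
    GridMismatchError
        If volume and mask differ in shape or spacing.
    EmptyMaskError
        If the label selects no voxels.
    """
    check_same_grid(volume, mask)
    sel = mask.data == label
    if not sel.any():
        raise EmptyMaskError(f"label {label} selects no voxels")
    return HuSample(volume.data[sel], volume.voxel_volume_mm3)


def percent_volume_at_or_above(sample: HuSample, threshold: float) -> float:
    """V_T: percent of the sample with HU >= threshold, in [0, 100]."""
    return 100.0 * float(np.count_nonzero(sample.values >= threshold)) / sample.n


def density_curve(sample: HuSample, grid=DEFAULT_CURVE_GRID) -> DensityCurve:
    """Cumulative density curve: percent at or above each threshold of an
    ascending HU grid."""
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("threshold grid must be nonempty")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("threshold grid must be strictly ascending")
    # one sort, then vectorized counts of values >= T via searchsorted
    ordered = np.sort(sample.values)
    n_below = np.searchsorted(ordered, grid, side="left")
    percent = 100.0 * (sample.n - n_below) / sample.n
    return DensityCurve(grid, percent)


def hu_percentile(sample: HuSample, q: float) -> float:
    """The q-th percentile of the HU values (linear interpolation between
    order statistics); q = 50 is the median HU50."""
    if not 0.0 < q < 100.0:
        raise ValueError(f"percentile q must be in (0, 100), got {q}")
    return float(np.percentile(sample.values, q))


def summarize(volume: VoxelVolume, mask: LungMask, label: int,
              thresholds=(), quantiles=()) -> DensitometrySummary:
    """Full densitometric summary of one lung.

    V(-200) and HU50 are always included regardless of the requested
    thresholds and quantiles.
    """
    sample = extract_hu(volume, mask, label)
    t_list = sorted(set(float(t) for t in thresholds) | {FIBROSIS_THRESHOLD_HU})
    q_list = sorted(set(float(q) for q in quantiles) | {50.0})
    v_map = {t: percent_volume_at_or_above(sample, t) for t in t_list}
    percentiles = {q: hu_percentile(sample, q) for q in q_list}
    return DensitometrySummary(v_map=v_map, percentiles=percentiles,
                               lung_volume_mm3=sample.total_volume_mm3,
                               n_voxels=sample.n)
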