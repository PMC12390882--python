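"""Reference bone volume fraction by pooled Otsu thresholding.

The reference standard mimics high-resolution micro-CT practice: a global
Otsu threshold is computed per sample, the per-sample thresholds are averaged
into one pooled threshold, and that single threshold segments every sample's
cylindrical VOI into bone and non-bone voxels.  BV/TV is then a plain voxel
count ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .phantom import VOIGeometry
from .simulate import HUImage

__all__ = [
    "SegmentationResult",
    "DegenerateInputError",
    "otsu_threshold",
    "pooled_threshold",
    "reference_bvtv",
]


class DegenerateInputError(ValueError):
    """Histogram has no contrast: Otsu threshold is undefined."""


@dataclass(frozen=True)
class SegmentationResult:
    threshold: float
    bone_voxels: int
    total_voxels: int

    @property
    def bvtv(self) -> float:
        return self.bone_voxels / self.total_voxels


def _histogram(values: np.ndarray, bins: int, percentile_range: tuple[float, float]):
    lo, hi = np.percentile(values, percentile_range)
    if not hi > lo:
        raise DegenerateInputError("value range collapses under percentile clipping")
    counts, edges = np.histogram(np.clip(values, lo, hi), bins=bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    return counts, centers


def otsu_threshold(
    values,
    bins: int = 256,
    percentile_range: tuple[float, float] = (0.1, 99.9),
) -> float:
    """Threshold maximising between-class variance of the value histogram.

    The histogram uses ``bins`` equal-width bins spanning the clipped
    percentile range (robust against isolated extreme values); candidate
    thresholds are the bin midpoints and ties resolve toward the lower one.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or np.unique(values).size < 2:
        raise DegenerateInputError("need at least two distinct values")
    counts, centers = _histogram(values, bins, percentile_range)
    return float(threshold_otsu(hist=(counts, centers)))


def pooled_threshold(
    per_sample_values: Iterable,
    bins: int = 256,
    percentile_range: tuple[float, float] = (0.1, 99.9),
) -> float:
    """Arithmetic mean of per-sample Otsu thresholds.

    The pooled value is applied uniformly to every sample downstream so that
    all samples are segmented consistently.
    """
    thresholds = [
        otsu_threshold(v, bins=bins, percentile_range=percentile_range)
        for v in per_sample_values
    ]
    if not thresholds:
        raise ValueError("need at least one sample")
    return float(np.mean(thresholds))


def reference_bvtv(
    image: HUImage,
    voi: VOIGeometry,
    threshold: float,
) -> SegmentationResult:
    """Voxel-count BV/TV inside the VOI at a fixed threshold.

    Voxels strictly above the threshold count as bone.
    """
    mask = voi.mask(image.grid.shape, image.spacing)
    total = int(mask.sum())
    if total == 0:
        raise ValueError("VOI contains no voxels")
    bone = int((image.grid[mask] > threshold).sum())
    return SegmentationResult(threshold=float(threshold), bone_voxels=bone, total_voxels=total)


def bvtv_from_counts(values: Sequence[float], counts: Sequence[int], threshold: float) -> SegmentationResult:
    """BV/TV from a (value, count) summary of VOI voxels.

    Equivalent to :func:`reference_bvtv` when the summary is exact (e.g. the
    unique values of a noiseless image); used by the study driver to avoid
    holding all high-resolution voxels in memory.
    """
    values = np.asarray(values, dtype=float)
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("empty VOI summary")
    bone = int(counts[values > threshold].sum())
    return SegmentationResult(threshold=float(threshold), bone_voxels=bone, total_voxels=total)
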