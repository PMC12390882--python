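"""Phantom-calibrated quantitative CT estimation of BV/TV.

The single-energy pathway: average the HU of each calibration rod over the
slices spanned by the sample's VOI, regress the known rod densities
(mgHA/cm^3) on those HU means, map the VOI-mean HU through the fitted line to
a volumetric bone mineral density, and convert to a bone volume fraction by
dividing by 1200 mg/cm^3 (the mineral density of fully mineralised tissue
under the constant-mineralisation assumption).

Negative raw densities are preserved -- clipping happens only at reporting
time -- because a pore space of air drives the VOI mean far below the
calibration range and the size of that failure is itself a result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .phantom import VOIGeometry
from .simulate import HUImage, mean_hu_in_voi

__all__ = [
    "CalibrationResult",
    "QctEstimate",
    "SingularFitError",
    "rod_mean_hu",
    "calibrate",
    "qct_bvtv",
    "MINERALIZED_TISSUE_DENSITY",
]

#: vBMD of fully mineralised bone tissue, mgHA/cm^3
MINERALIZED_TISSUE_DENSITY = 1200.0


class SingularFitError(ValueError):
    """Calibration regression is degenerate (constant rod HU)."""


@dataclass(frozen=True)
class CalibrationResult:
    """HU-to-vBMD mapping fitted on the phantom rods.

    ``density = slope * HU + intercept`` with density in mgHA/cm^3.
    """

    slope: float
    intercept: float
    r_squared: float
    rod_means: tuple[float, ...]

    def vbmd(self, hu: float) -> float:
        return self.slope * hu + self.intercept


@dataclass(frozen=True)
class QctEstimate:
    mean_hu: float
    vbmd: float

    @property
    def bvtv(self) -> float:
        """Raw BV/TV (may fall outside [0, 1]; see ``bvtv_clipped``)."""
        return self.vbmd / MINERALIZED_TISSUE_DENSITY

    @property
    def bvtv_clipped(self) -> float:
        return float(np.clip(self.bvtv, 0.0, 1.0))


def rod_mean_hu(
    image: HUImage,
    rod_masks: Sequence[np.ndarray],
    voi: VOIGeometry,
) -> np.ndarray:
    """Per-rod mean HU restricted to the slices spanned by the VOI height."""
    nz = image.grid.shape[voi.axis]
    centers = (np.arange(nz) + 0.5) * image.spacing[voi.axis]
    in_span = np.abs(centers - voi.center[voi.axis]) <= voi.height / 2
    if not in_span.any():
        raise ValueError("VOI height spans no slices")
    means = []
    slicer = [slice(None)] * 3
    slicer[voi.axis] = in_span
    for mask in rod_masks:
        sub = mask[tuple(slicer)]
        if not sub.any():
            raise ValueError("rod mask empty over the VOI slice range")
        means.append(float(image.grid[tuple(slicer)][sub].mean()))
    return np.asarray(means)


def calibrate(rod_hu: Sequence[float], rod_density: Sequence[float]) -> CalibrationResult:
    """Ordinary least squares fit of rod density (mgHA/cm^3) on rod HU."""
    hu = np.asarray(rod_hu, dtype=float)
    dens = np.asarray(rod_density, dtype=float)
    if hu.size != dens.size or hu.size < 2:
        raise ValueError("need >= 2 rods with matching densities")
    if np.ptp(hu) == 0:
        raise SingularFitError("rod HU values are constant; regression undefined")
    fit = stats.linregress(hu, dens)
    return CalibrationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        rod_means=tuple(hu),
    )


def qct_bvtv(
    image: HUImage,
    voi: VOIGeometry,
    calibration: CalibrationResult,
) -> QctEstimate:
    """BV/TV from the VOI-mean HU through the phantom calibration line."""
    hu = mean_hu_in_voi(image, voi)
    return QctEstimate(mean_hu=hu, vbmd=calibration.vbmd(hu))
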