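"""Forward simulation of HU images from fraction maps.

Two image families are produced from the same monoenergetic mixture model:
virtual monochromatic images (VMI) at a chosen photon energy, standing in for
spectral CT (dual-energy or photon-counting) reconstructions, and a
single-effective-energy image standing in for conventional quantitative CT.

Noise is independent Gaussian per voxel with a standard deviation that scales
inversely with the square root of dose (CTDI_v) and, optionally, with photon
energy -- the latter captures the low-keV noise amplification of
scintillator-based dual-energy VMIs relative to photon-counting ones.  No
spatial correlation, beam hardening or scatter is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .materials import DEFAULT_CONSTANTS, HUModelConstants, Material, _library, alpha
from .phantom import FractionVolume, VOIGeometry

__all__ = ["NoiseModel", "HUImage", "simulate_vmi", "simulate_qct", "mean_hu_in_voi"]

VMI_ENERGY_RANGE = (40.0, 140.0)


@dataclass(frozen=True)
class NoiseModel:
    """Dose- and energy-dependent Gaussian image noise.

    sigma(ctdi, E) = modality_factor * sigma_ref
                     * (energy_ref / E) ** energy_exponent
                     * sqrt(ctdi_ref / ctdi)

    The reference level ``sigma_ref`` is the voxel SD at ``ctdi_ref`` and
    ``energy_ref``.  Presets: the dual-energy preset amplifies noise at low
    keV (exponent 1); the photon-counting preset is energy-flat and lower
    overall, reflecting the better dose efficiency of counting detectors.
    """

    sigma_ref: float = 15.0
    ctdi_ref: float = 22.3
    energy_ref: float = 70.0
    energy_exponent: float = 0.0
    modality_factor: float = 1.0

    def sigma(self, ctdi: float, energy_kev: float) -> float:
        if ctdi <= 0:
            raise ValueError("ctdi must be > 0")
        return (
            self.modality_factor
            * self.sigma_ref
            * (self.energy_ref / energy_kev) ** self.energy_exponent
            * np.sqrt(self.ctdi_ref / ctdi)
        )

    @classmethod
    def dect(cls, sigma_ref: float = 15.0) -> "NoiseModel":
        return cls(sigma_ref=sigma_ref, energy_exponent=1.0, modality_factor=1.0)

    @classmethod
    def pct(cls, sigma_ref: float = 15.0) -> "NoiseModel":
        return cls(sigma_ref=sigma_ref, energy_exponent=0.0, modality_factor=0.6)

    @classmethod
    def qct(cls, sigma_ref: float = 15.0) -> "NoiseModel":
        return cls(sigma_ref=sigma_ref, energy_exponent=0.0, modality_factor=1.0)

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(sigma_ref=0.0)


@dataclass
class HUImage:
    """A simulated CT volume in Hounsfield units plus acquisition metadata."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    modality: str  # "VMI" or "QCT"
    energy_kev: float
    ctdi: float
    noise_sigma: float
    seed: int | None = None
    kvp: float | str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _forward_hu(
    fractions: FractionVolume,
    energy_kev: float,
    library,
    constants: HUModelConstants,
) -> np.ndarray:
    lib = _library(library)
    coeffs = np.array(
        [
            lib[c].density * alpha(lib[c], energy_kev, library=lib, constants=constants)
            for c in fractions.components
        ],
        dtype=np.float64,
    )
    hu = np.tensordot(coeffs, fractions.grid.astype(np.float64), axes=(0, 0))
    return hu - constants.theta


def _simulate(
    fractions: FractionVolume,
    energy_kev: float,
    noise: NoiseModel,
    ctdi: float,
    seed,
    modality: str,
    library,
    constants: HUModelConstants,
    kvp,
) -> HUImage:
    hu = _forward_hu(fractions, energy_kev, library, constants)
    sigma = noise.sigma(ctdi, energy_kev) if noise.sigma_ref > 0 else 0.0
    if sigma > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, sigma, size=hu.shape)
    return HUImage(
        grid=hu,
        spacing=fractions.spacing,
        modality=modality,
        energy_kev=energy_kev,
        ctdi=ctdi,
        noise_sigma=float(sigma),
        seed=seed if np.isscalar(seed) else None,
        kvp=kvp,
    )


def simulate_vmi(
    fractions: FractionVolume,
    energy_kev: float,
    noise: NoiseModel = NoiseModel.noiseless(),
    ctdi: float = 22.3,
    seed=0,
    *,
    library=None,
    constants: HUModelConstants = DEFAULT_CONSTANTS,
    kvp=None,
) -> HUImage:
    """Virtual monochromatic image at ``energy_kev`` (40-140 keV)."""
    lo, hi = VMI_ENERGY_RANGE
    if not lo <= energy_kev <= hi:
        raise ValueError(f"VMI energy must be within [{lo}, {hi}] keV")
    return _simulate(fractions, energy_kev, noise, ctdi, seed, "VMI", library, constants, kvp)


def simulate_qct(
    fractions: FractionVolume,
    effective_energy_kev: float = 65.0,
    noise: NoiseModel = NoiseModel.noiseless(),
    ctdi: float = 22.3,
    seed=0,
    *,
    library=None,
    constants: HUModelConstants = DEFAULT_CONSTANTS,
    kvp: float = 120.0,
) -> HUImage:
    """Single-energy image at the polychromatic protocol's effective energy.

    The default of 65 keV corresponds to a 120 kVp tube spectrum by the usual
    effective-energy rule of thumb (roughly 55% of the peak voltage).
    """
    return _simulate(
        fractions, effective_energy_kev, noise, ctdi, seed, "QCT", library, constants, kvp
    )


def voi_hu_values(
    fractions: FractionVolume,
    energy_kev: float,
    voi: VOIGeometry,
    *,
    library=None,
    constants: HUModelConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Noiseless forward-model HU of the voxels inside a VOI.

    Identical to simulating the full image and masking, but only touches the
    VOI voxels; used for high-resolution reference scans where the full image
    would be needlessly large.
    """
    lib = _library(library)
    mask = voi.mask(fractions.shape, fractions.spacing)
    out = np.full(int(mask.sum()), -constants.theta, dtype=np.float64)
    for c, grid in zip(fractions.components, fractions.grid):
        mat = lib[c]
        coeff = mat.density * alpha(mat, energy_kev, library=lib, constants=constants)
        out += coeff * grid[mask].astype(np.float64)
    return out


def mean_hu_in_voi(image: HUImage, voi: VOIGeometry) -> float:
    """Arithmetic mean HU over voxels whose centers fall inside the cylinder."""
    mask = voi.mask(image.grid.shape, image.spacing)
    if not mask.any():
        raise ValueError("VOI contains no voxels")
    return float(image.grid[mask].mean())
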