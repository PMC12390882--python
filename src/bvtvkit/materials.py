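"""Material library and the monoenergetic HU mixture model.

A CT voxel containing a mixture of materials attenuates according to the
volume-fraction-weighted sum of the component attenuations.  On the
Hounsfield scale this reads

    HU(E) = sum_i rho_i * alpha_i(E) * phi_i - Theta

where ``rho_i`` is the physical density (g/cm^3), ``phi_i`` the volume
fraction, ``Theta`` a scanner constant close to 1000, and ``alpha_i(E)`` the
mass attenuation coefficient of component *i* normalised by that of water and
scaled so that water itself evaluates to Theta.  A voxel of pure unit-density
water then gives HU = 0 at every energy, and vacuum gives -Theta.

Trabecular bone is modelled with a fixed-composition "matrix" composite of
collagen and hydroxyapatite whose average density (1.92 g/cm^3) pins down the
unique volume split between the two constituents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "AttenuationTable",
    "Material",
    "HUModelConstants",
    "MatrixComposition",
    "EnergyRangeError",
    "load_attenuation_table",
    "load_material",
    "default_library",
    "matrix_composition",
    "alpha",
    "hu_of_mixture",
    "DEFAULT_CONSTANTS",
]

_DATA_PACKAGE = "bvtvkit.data.attenuation"

#: densities of the default library components, g/cm^3
DENSITIES = {
    "water": 1.000,
    "air": 0.0013,
    "saline": 1.005,
    "fat": 0.92,
    "collagen": 1.2,
    "hydroxyapatite": 3.06,
    "matrix": 1.92,
}

#: table file backing each default component
_TABLE_FILES = {
    "water": "water.txt",
    "air": "air.txt",
    "saline": "saline.txt",
    "fat": "adipose.txt",
    "collagen": "collagen.txt",
    "hydroxyapatite": "hydroxyapatite.txt",
}


class EnergyRangeError(ValueError):
    """Requested photon energy lies outside the tabulated range."""


@dataclass(frozen=True)
class AttenuationTable:
    """Energy-indexed mass attenuation coefficients.

    Parameters
    ----------
    energies
        Photon energies in keV, strictly increasing.
    mu_over_rho
        Mass attenuation coefficients in cm^2/g, one per energy, all > 0.
    """

    energies: np.ndarray
    mu_over_rho: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        m = np.asarray(self.mu_over_rho, dtype=float)
        if e.ndim != 1 or m.shape != e.shape:
            raise ValueError("energies and mu_over_rho must be 1-D and equally long")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energies must be strictly increasing")
        if not np.all(m > 0):
            raise ValueError("mass attenuation coefficients must be positive")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu_over_rho", m)

    def __call__(self, energy_kev):
        """Interpolate mu/rho at ``energy_kev`` (log-log, no extrapolation)."""
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self.energies[0], self.energies[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise EnergyRangeError(
                f"energy {energy_kev} keV outside table range [{lo}, {hi}] keV"
            )
        out = np.exp(
            np.interp(np.log(e), np.log(self.energies), np.log(self.mu_over_rho))
        )
        return float(out) if np.isscalar(energy_kev) else out


@dataclass(frozen=True)
class Material:
    """A named material with density (g/cm^3) and attenuation table."""

    name: str
    density: float
    attenuation: AttenuationTable

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError(f"density of {self.name!r} must be >= 0")


@dataclass(frozen=True)
class HUModelConstants:
    """Scanner constants of the HU mixture model.

    ``theta`` is the Hounsfield offset (1000 for virtually all scanners);
    ``alpha_scale`` scales the water-normalised attenuation ratio so that pure
    unit-density water yields HU = 0, which requires alpha_scale == theta.
    """

    theta: float = 1000.0
    alpha_scale: float = 1000.0


DEFAULT_CONSTANTS = HUModelConstants()


def load_attenuation_table(source) -> AttenuationTable:
    """Load a two-column (keV, cm^2/g) plain-text table.

    Lines starting with ``#`` are comments.  ``source`` may be a path or an
    open text file.
    """
    if hasattr(source, "read"):
        data = np.loadtxt(source)
    else:
        data = np.loadtxt(Path(source))
    data = np.atleast_2d(data)
    return AttenuationTable(energies=data[:, 0], mu_over_rho=data[:, 1])


def _packaged_table(filename: str) -> AttenuationTable:
    ref = resources.files(_DATA_PACKAGE).joinpath(filename)
    with ref.open("r") as fh:
        return load_attenuation_table(fh)


def load_material(name: str, density: float | None = None) -> Material:
    """Load a packaged material by table file stem (e.g. ``"pmma"``)."""
    dens = DENSITIES.get(name) if density is None else density
    if dens is None:
        defaults = {"pmma": 1.19, "nacl": 2.165, "adipose": 0.92}
        dens = defaults.get(name)
    if dens is None:
        raise KeyError(f"no default density for material {name!r}; pass density=")
    return Material(name=name, density=dens, attenuation=_packaged_table(f"{name}.txt"))


@dataclass(frozen=True)
class MatrixComposition:
    """Volume and mass split of the collagen/hydroxyapatite bone matrix."""

    volume_fraction_ha: float
    volume_fraction_collagen: float
    mass_fraction_ha: float
    mass_fraction_collagen: float


def matrix_composition(
    rho_ha: float = DENSITIES["hydroxyapatite"],
    rho_collagen: float = DENSITIES["collagen"],
    rho_matrix: float = DENSITIES["matrix"],
) -> MatrixComposition:
    """Solve for the unique HA/collagen split consistent with the matrix density.

    The two constituents fill the composite completely (v_ha + v_col = 1) and
    their density-weighted volumes reproduce the composite density
    (v_ha * rho_ha + v_col * rho_col = rho_matrix).
    """
    if rho_ha == rho_collagen:
        raise ValueError("constituent densities must differ")
    v_ha = (rho_matrix - rho_collagen) / (rho_ha - rho_collagen)
    v_col = 1.0 - v_ha
    m_ha = v_ha * rho_ha / rho_matrix
    m_col = v_col * rho_collagen / rho_matrix
    return MatrixComposition(
        volume_fraction_ha=v_ha,
        volume_fraction_collagen=v_col,
        mass_fraction_ha=m_ha,
        mass_fraction_collagen=m_col,
    )


def _matrix_table(composition: MatrixComposition | None = None) -> AttenuationTable:
    """Mass-fraction-weighted mu/rho of the collagen + HA composite."""
    comp = composition or matrix_composition()
    ha = _packaged_table(_TABLE_FILES["hydroxyapatite"])
    col = _packaged_table(_TABLE_FILES["collagen"])
    if not np.array_equal(ha.energies, col.energies):
        raise ValueError("constituent tables must share an energy grid")
    mu = comp.mass_fraction_ha * ha.mu_over_rho + comp.mass_fraction_collagen * col.mu_over_rho
    return AttenuationTable(energies=ha.energies, mu_over_rho=mu)


def default_library() -> dict[str, Material]:
    """The default component library: water, air, saline, fat, collagen,
    hydroxyapatite and the collagen/HA matrix composite."""
    lib = {
        name: Material(name, DENSITIES[name], _packaged_table(fn))
        for name, fn in _TABLE_FILES.items()
    }
    lib["matrix"] = Material("matrix", DENSITIES["matrix"], _matrix_table())
    return lib


_DEFAULT_LIBRARY: dict[str, Material] | None = None


def _library(library: Mapping[str, Material] | None) -> Mapping[str, Material]:
    """Resolve the component lookup used by the mixture model.

    The implicit default is the seven-component library extended with the
    auxiliary holder material (PMMA), so scenes assembled with the default
    holder simulate without an explicit library argument.
    """
    global _DEFAULT_LIBRARY
    if library is not None:
        return library
    if _DEFAULT_LIBRARY is None:
        lib = default_library()
        lib["pmma"] = load_material("pmma")
        _DEFAULT_LIBRARY = lib
    return _DEFAULT_LIBRARY


def alpha(
    material: Material | str,
    energy_kev,
    *,
    library: Mapping[str, Material] | None = None,
    constants: HUModelConstants = DEFAULT_CONSTANTS,
):
    """Water-normalised CT coefficient of ``material`` at ``energy_kev``.

    Returns ``alpha_scale * (mu/rho)_material(E) / (mu/rho)_water(E)``; with
    the default constants water itself gives exactly 1000 at every energy.
    """
    lib = _library(library)
    if isinstance(material, str):
        material = lib[material]
    water = lib["water"]
    ratio = np.asarray(material.attenuation(energy_kev)) / np.asarray(
        water.attenuation(energy_kev)
    )
    out = constants.alpha_scale * ratio
    return float(out) if np.isscalar(energy_kev) else out


def hu_of_mixture(
    fractions: Mapping[str, float],
    energy_kev: float,
    *,
    library: Mapping[str, Material] | None = None,
    constants: HUModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """HU of a voxel holding the given component volume fractions.

    Fractions must lie in [0, 1] and sum to at most 1 (any remainder is
    treated as vacuum, contributing only the -Theta offset).  Unknown
    component names raise ``KeyError``.
    """
    lib = _library(library)
    total = 0.0
    hu = -constants.theta
    for name, phi in fractions.items():
        mat = lib[name]  # KeyError on unknown component
        if phi < 0 or phi > 1:
            raise ValueError(f"fraction of {name!r} must be in [0, 1], got {phi}")
        total += phi
        hu += mat.density * alpha(mat, energy_kev, library=lib, constants=constants) * phi
    if total > 1 + 1e-9:
        raise ValueError(f"fractions sum to {total} > 1")
    return hu
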