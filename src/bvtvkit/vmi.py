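"""Phantom-less BV/TV from virtual monochromatic images.

At each reconstruction energy the VOI-mean HU is one linear equation in the
unknown component volume fractions (the monoenergetic mixture model); a final
volume-conservation row states that the fractions fill the VOI.  With the
default four energies (40, 60, 80, 100 keV) this yields an overdetermined
5-row system per fluid group:

* fat group:    unknowns (BV/TV, phi_fat, phi_air);    phi_saline = 0
* saline group: unknowns (BV/TV, phi_saline, phi_air); phi_fat = 0
* air group:    unknowns (BV/TV, phi_air);             both fluids = 0

The air group nominally has three unknowns, but with both fluids zeroed the
fluid column duplicates the air column and the system loses rank, so it is
posed with two.  The system is solved by weighted linear least squares with
[0, 1] bounds on every unknown (``scipy.optimize.lsq_linear``).

Row weighting: energy rows carry unit weight; the conservation row, whose raw
coefficients are O(1) against energy rows of O(1000), is scaled by the mean
Euclidean norm of the energy rows times a configurable factor (default 1) so
that volume conservation is enforced on the same footing as the HU data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import lsq_linear

from .materials import DEFAULT_CONSTANTS, HUModelConstants, _library, alpha
from .phantom import VOIGeometry
from .simulate import HUImage, mean_hu_in_voi

__all__ = [
    "DEFAULT_ENERGIES",
    "SpectralMeasurement",
    "DecompositionSystem",
    "VmiEstimate",
    "build_system",
    "solve",
    "vmi_bvtv",
]

#: the energy combination found most stable for this decomposition
DEFAULT_ENERGIES = (40.0, 60.0, 80.0, 100.0)

_GROUP_UNKNOWNS = {
    "fat": ("bvtv", "fat", "air"),
    "saline": ("bvtv", "saline", "air"),
    "air": ("bvtv", "air"),
}


@dataclass(frozen=True)
class SpectralMeasurement:
    """VOI-mean HU at several reconstruction energies."""

    energies: tuple[float, ...]
    mean_hu: tuple[float, ...]
    voi: VOIGeometry | None = None

    def __post_init__(self) -> None:
        if len(self.energies) != len(self.mean_hu):
            raise ValueError("energies and mean_hu must have equal length")
        if not all(b > a for a, b in zip(self.energies, self.energies[1:])):
            raise ValueError("energies must be strictly increasing")


@dataclass
class DecompositionSystem:
    """The bounded weighted least-squares problem for one fluid group.

    ``matrix`` has one row per energy plus the conservation row; ``weights``
    multiply the squared residual of each row in the objective.
    """

    matrix: np.ndarray
    rhs: np.ndarray
    unknowns: tuple[str, ...]
    weights: np.ndarray
    bounds: tuple[float, float] = (0.0, 1.0)


@dataclass(frozen=True)
class VmiEstimate:
    bvtv: float
    phi_fluid: float
    phi_air: float
    residual_norm: float
    active_bounds: frozenset[str]
    rank_deficient: bool = False


def build_system(
    measurement: SpectralMeasurement,
    fluid_group: str,
    *,
    library=None,
    constants: HUModelConstants = DEFAULT_CONSTANTS,
    conservation_weight_factor: float = 1.0,
) -> DecompositionSystem:
    """Assemble the per-fluid-group linear system from spectral HU means."""
    if fluid_group not in _GROUP_UNKNOWNS:
        raise ValueError(
            f"unknown fluid group {fluid_group!r}; expected one of {sorted(_GROUP_UNKNOWNS)}"
        )
    if len(measurement.energies) < 2:
        raise ValueError("need at least two energies")
    lib = _library(library)
    unknowns = _GROUP_UNKNOWNS[fluid_group]
    rows, rhs = [], []
    for e, hu in zip(measurement.energies, measurement.mean_hu):
        row = []
        for u in unknowns:
            comp = "matrix" if u == "bvtv" else u
            mat = lib[comp]
            row.append(mat.density * alpha(mat, e, library=lib, constants=constants))
        rows.append(row)
        rhs.append(hu + constants.theta)
    a = np.asarray(rows, dtype=float)
    # conservation of volume: the fractions fill the VOI
    a = np.vstack([a, np.ones((1, len(unknowns)))])
    rhs.append(1.0)
    mean_norm = float(np.mean(np.linalg.norm(a[:-1], axis=1)))
    weights = np.ones(a.shape[0])
    weights[-1] = (conservation_weight_factor * mean_norm) ** 2
    return DecompositionSystem(
        matrix=a,
        rhs=np.asarray(rhs, dtype=float),
        unknowns=unknowns,
        weights=weights,
    )


def solve(system: DecompositionSystem) -> VmiEstimate:
    """Minimise the weighted residual subject to [0, 1] bounds.

    Deterministic; reports the weighted residual norm and which bounds are
    active.  Rank deficiency of the design matrix is flagged, not fatal: the
    bounds keep the problem well posed.
    """
    sw = np.sqrt(system.weights)
    aw = system.matrix * sw[:, None]
    bw = system.rhs * sw
    res = lsq_linear(aw, bw, bounds=system.bounds, method="bvls", tol=1e-14)
    x = res.x
    est = dict(zip(system.unknowns, x))
    active = frozenset(
        u
        for u, v in est.items()
        if v <= system.bounds[0] + 1e-9 or v >= system.bounds[1] - 1e-9
    )
    fluid_names = [u for u in system.unknowns if u not in ("bvtv", "air")]
    return VmiEstimate(
        bvtv=float(est["bvtv"]),
        phi_fluid=float(est[fluid_names[0]]) if fluid_names else 0.0,
        phi_air=float(est.get("air", 0.0)),
        residual_norm=float(np.linalg.norm(aw @ x - bw)),
        active_bounds=active,
        rank_deficient=np.linalg.matrix_rank(system.matrix) < len(system.unknowns),
    )


def vmi_bvtv(
    images: Mapping[float, HUImage] | Sequence[HUImage],
    voi: VOIGeometry,
    fluid_group: str,
    *,
    library=None,
    constants: HUModelConstants = DEFAULT_CONSTANTS,
    conservation_weight_factor: float = 1.0,
) -> VmiEstimate:
    """Whole-procedure composition: VOI means -> system -> bounded solve."""
    if isinstance(images, Mapping):
        pairs = sorted(images.items())
        energies = [e for e, _ in pairs]
        imgs = [im for _, im in pairs]
    else:
        imgs = sorted(images, key=lambda im: im.energy_kev)
        energies = [im.energy_kev for im in imgs]
    ref = imgs[0]
    for im in imgs[1:]:
        if im.grid.shape != ref.grid.shape or not np.allclose(im.spacing, ref.spacing):
            raise ValueError("all per-energy images must share grid and spacing")
    measurement = SpectralMeasurement(
        energies=tuple(energies),
        mean_hu=tuple(mean_hu_in_voi(im, voi) for im in imgs),
        voi=voi,
    )
    system = build_system(
        measurement,
        fluid_group,
        library=library,
        constants=constants,
        conservation_weight_factor=conservation_weight_factor,
    )
    return solve(system)
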