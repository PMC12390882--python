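"""Synthetic trabecular specimens, fluid fills and the calibration phantom.

The generator stands in for physical bone biopsies: cylindrical cores of
trabecular bone (13 mm diameter, lengths around 8-11 mm, bone volume
fractions 17-40%) whose intertrabecular space is emptied and refilled with a
marrow-substitute fluid (air, 0.9% saline or an adipose surrogate), scanned
next to a six-rod hydroxyapatite calibration phantom.

Trabecular texture is modelled as a thresholded, smoothed Gaussian random
field.  That reproduces the two features the downstream estimators actually
see -- a binary matrix/pore microstructure with a controllable volume
fraction and a tunable characteristic strut scale -- without attempting
anatomical plate/rod realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "VOIGeometry",
    "FractionVolume",
    "CalibrationPhantomSpec",
    "Scene",
    "LayoutError",
    "generate_trabecular",
    "fill_pores",
    "downsample_to_grid",
    "assemble_scene",
]

FLUIDS = ("air", "saline", "fat")


class LayoutError(ValueError):
    """Scene placement is invalid (too many samples or overlapping)."""


@dataclass(frozen=True)
class VOIGeometry:
    """A cylindrical measurement region.

    The cylinder axis runs along one grid axis (default the slice axis 0);
    ``center`` is in physical mm, with voxel centers at (index + 0.5) * spacing.
    """

    diameter: float
    height: float
    center: tuple[float, float, float]
    axis: int = 0

    def mask(self, shape: Sequence[int], spacing: Sequence[float]) -> np.ndarray:
        """Boolean mask of voxels whose centers fall inside the cylinder."""
        coords = [
            (np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)
        ]
        grids = np.meshgrid(*coords, indexing="ij", sparse=True)
        axial = np.abs(grids[self.axis] - self.center[self.axis]) <= self.height / 2
        trans = [i for i in range(3) if i != self.axis]
        r2 = sum((grids[i] - self.center[i]) ** 2 for i in trans)
        return axial & (r2 <= (self.diameter / 2) ** 2)


@dataclass
class FractionVolume:
    """Per-voxel component volume fractions on a regular grid.

    ``grid`` has shape (n_components, nz, ny, nx), indexed (slice, row,
    column); fractions are in [0, 1] and sum to 1 on every voxel.
    ``ground_truth_bvtv``, when set, is the mean matrix fraction over the
    volume's measurement VOI.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    components: tuple[str, ...]
    ground_truth_bvtv: float | None = None
    voi: VOIGeometry | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 4 or self.grid.shape[0] != len(self.components):
            raise ValueError("grid must have shape (n_components, nz, ny, nx)")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape[1:]

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def component(self, name: str) -> np.ndarray:
        return self.grid[self.components.index(name)]

    def validate(self, tol: float = 1e-6) -> None:
        if self.grid.min() < -tol or self.grid.max() > 1 + tol:
            raise ValueError("fractions outside [0, 1]")
        sums = self.grid.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("voxel fractions do not sum to 1")

    def mean_fraction_in_voi(self, name: str, voi: VOIGeometry | None = None) -> float:
        voi = voi or self.voi
        if voi is None:
            raise ValueError("no VOI supplied")
        mask = voi.mask(self.shape, self.spacing)
        if not mask.any():
            raise ValueError("VOI contains no voxels")
        return float(self.component(name)[mask].mean())


@dataclass(frozen=True)
class CalibrationPhantomSpec:
    """Six-rod hydroxyapatite density calibration phantom.

    Rod densities are equivalent HA concentrations in mg/cm^3; each rod is a
    cylinder of HA dispersed in a water-equivalent background, running along
    the slice axis.
    """

    rod_densities: tuple[float, ...] = (0.0, 100.0, 200.0, 400.0, 600.0, 800.0)
    rod_radius: float = 6.0
    rod_gap: float = 3.0
    background: str = "water"

    def ha_fraction(self, density_mg_cm3: float) -> float:
        """HA volume fraction equivalent to a rod concentration."""
        from .materials import DENSITIES

        return density_mg_cm3 / 1000.0 / DENSITIES["hydroxyapatite"]


def _default_voi(size: Sequence[float], voi_diameter: float, voi_margin: float) -> VOIGeometry:
    sz, sy, sx = (float(v) for v in size)
    return VOIGeometry(
        diameter=voi_diameter,
        height=sz - 2 * voi_margin,
        center=(sz / 2, sy / 2, sx / 2),
        axis=0,
    )


def generate_trabecular(
    target_bvtv: float,
    size: Sequence[float],
    spacing: float,
    correlation_length: float = 0.6,
    seed: int | np.random.SeedSequence = 0,
    voi_diameter: float = 12.5,
    voi_margin: float = 0.5,
) -> FractionVolume:
    """Generate a binary matrix/pore trabecular block.

    A Gaussian random field is smoothed to the requested correlation length
    and thresholded at the quantile that yields ``target_bvtv``; the achieved
    matrix fraction is therefore within one voxel-count quantum of the target.
    Deterministic for a fixed seed.

    Parameters
    ----------
    target_bvtv
        Desired matrix volume fraction, in (0, 1).
    size
        Physical block size (z, y, x) in mm; z is the cylinder/slice axis.
    spacing
        Isotropic voxel size in mm.  Reference-grade volumes use <= 0.1 mm.
    correlation_length
        Characteristic trabecular scale in mm; must be at least twice the
        voxel size to be resolvable.
    """
    if not 0 < target_bvtv < 1:
        raise ValueError("target_bvtv must be in (0, 1)")
    if correlation_length < 2 * spacing:
        raise ValueError(
            f"correlation_length {correlation_length} mm unresolvable at "
            f"{spacing} mm spacing (needs >= 2 voxels)"
        )
    shape = tuple(max(1, round(s / spacing)) for s in size)
    rng = np.random.default_rng(seed)
    fld = rng.standard_normal(shape).astype(np.float32)
    sigma = correlation_length / spacing / 2.0  # filter sigma = half the strut scale
    fld = ndimage.gaussian_filter(fld, sigma=sigma, mode="wrap")
    thr = np.quantile(fld, 1.0 - target_bvtv)
    matrix = (fld > thr).astype(np.float32)
    grid = np.stack([matrix, 1.0 - matrix])
    vol = FractionVolume(
        grid=grid,
        spacing=(spacing,) * 3,
        components=("matrix", "pore"),
        voi=_default_voi([n * spacing for n in shape], voi_diameter, voi_margin),
    )
    vol.ground_truth_bvtv = vol.mean_fraction_in_voi("matrix")
    return vol


def fill_pores(
    volume: FractionVolume,
    fluid: str,
    residual_air_fraction: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    bubble_correlation_length: float = 0.8,
) -> FractionVolume:
    """Assign the pore space to a marrow-substitute fluid.

    A ``residual_air_fraction`` share of the pore volume is left as air, in
    correlated blobs (smoothed-noise quantile), emulating bubbles that remain
    after filling.  The matrix phase is untouched.
    """
    if fluid not in FLUIDS:
        raise ValueError(f"unknown fluid {fluid!r}; expected one of {FLUIDS}")
    if not 0 <= residual_air_fraction < 1:
        raise ValueError("residual_air_fraction must be in [0, 1)")
    matrix = volume.component("matrix")
    pore = volume.component("pore")
    if fluid == "air" or residual_air_fraction == 0:
        air = pore if fluid == "air" else np.zeros_like(pore)
        flu = np.zeros_like(pore) if fluid == "air" else pore
    else:
        rng = np.random.default_rng(seed)
        fld = rng.standard_normal(volume.shape).astype(np.float32)
        sigma = bubble_correlation_length / volume.spacing[0] / 2.0
        fld = ndimage.gaussian_filter(fld, sigma=sigma, mode="wrap")
        pore_mask = pore > 0.5
        vals = fld[pore_mask]
        thr = np.quantile(vals, 1.0 - residual_air_fraction)
        bubble = pore_mask & (fld > thr)
        air = bubble.astype(np.float32)
        flu = pore - air
    comps = ("matrix", fluid, "air") if fluid != "air" else ("matrix", "air")
    grids = [matrix, flu, air] if fluid != "air" else [matrix, air]
    return FractionVolume(
        grid=np.stack(grids),
        spacing=volume.spacing,
        components=comps,
        ground_truth_bvtv=volume.ground_truth_bvtv,
        voi=volume.voi,
    )


def _overlap_matrix(n_src: int, s_src: float, n_tgt: int) -> tuple[np.ndarray, float]:
    """Exact-partition box-average weights from a source axis to a target axis.

    The target grid tiles the source extent exactly (n_tgt voxels of size
    extent / n_tgt), so fractions stay normalised and component volume is
    conserved to floating point.
    """
    extent = n_src * s_src
    s_tgt = extent / n_tgt
    w = np.zeros((n_tgt, n_src))
    for j in range(n_tgt):
        lo, hi = j * s_tgt, (j + 1) * s_tgt
        i0, i1 = int(lo / s_src), min(int(np.ceil(hi / s_src)), n_src)
        for i in range(i0, i1):
            ov = min(hi, (i + 1) * s_src) - max(lo, i * s_src)
            if ov > 0:
                w[j, i] = ov / s_tgt
    return w, s_tgt


def downsample_to_grid(
    volume: FractionVolume,
    pixel: float,
    slice_thickness: float,
) -> FractionVolume:
    """Volume-weighted resampling to a clinical-resolution grid.

    Each target voxel's fractions are the exact volume average of the source
    fractions over its footprint (the partial-volume model).  The number of
    target voxels per axis is chosen so the target grid tiles the source
    extent exactly; the recorded spacing is therefore the requested value
    rounded to the nearest exact divisor of the extent (within half a voxel).
    """
    targets = (slice_thickness, pixel, pixel)
    mats, spac = [], []
    for ax, t in enumerate(targets):
        if t < volume.spacing[ax]:
            raise ValueError("target spacing must be >= source spacing")
        n_src = volume.shape[ax]
        n_tgt = max(1, round(n_src * volume.spacing[ax] / t))
        if n_tgt < 1:
            raise ValueError("target grid smaller than one source voxel")
        w, s_t = _overlap_matrix(n_src, volume.spacing[ax], n_tgt)
        mats.append(w)
        spac.append(s_t)
    g = volume.grid
    for ax, w in enumerate(mats):
        g = np.moveaxis(np.tensordot(w.astype(np.float32), g, axes=(1, ax + 1)), 0, ax + 1)
        g = np.ascontiguousarray(g)
    return FractionVolume(
        grid=g,
        spacing=tuple(spac),
        components=volume.components,
        ground_truth_bvtv=volume.ground_truth_bvtv,
        voi=volume.voi,
    )


@dataclass
class Scene:
    """An assembled scan scene: stacked samples above the phantom rods."""

    volume: FractionVolume
    rod_masks: list[np.ndarray]
    vois: list[VOIGeometry]
    sample_slices: list[tuple[slice, slice, slice]]


def assemble_scene(
    samples: Sequence[FractionVolume],
    phantom: CalibrationPhantomSpec = CalibrationPhantomSpec(),
    holder_material: str = "pmma",
    sample_diameter: float = 13.0,
    gap: float = 2.0,
) -> Scene:
    """Place up to four samples and the calibration phantom in one scene.

    Samples (already on the scene's voxel grid) sit side by side along x with
    their cylinder axes along z; the phantom rods run along z underneath, as
    cylinders of HA-in-water rasterised by voxel centers.  Everything else is
    holder material.  VOI geometries are returned in scene coordinates.
    """
    if not samples:
        raise LayoutError("at least one sample required")
    if len(samples) > 4:
        raise LayoutError("at most 4 samples per stack")
    sp = samples[0].spacing
    for s in samples[1:]:
        if not np.allclose(s.spacing[1:], sp[1:], rtol=1e-6):
            raise LayoutError("samples must share in-plane spacing")
    sz, sy, sx = sp
    margin = gap

    # z extent: tallest sample plus a one-slice pad
    nz = max(s.shape[0] for s in samples) + 2
    # x: samples side by side; rods side by side
    sample_w = max(s.shape[2] * s.spacing[2] for s in samples)
    rod_d = 2 * phantom.rod_radius
    n_rod = len(phantom.rod_densities)
    width = max(
        len(samples) * (sample_w + gap) + gap,
        n_rod * (rod_d + phantom.rod_gap) + phantom.rod_gap,
    ) + 2 * margin
    # y: sample diameter row + gap + rod row
    depth = sample_diameter + gap + rod_d + 2 * margin
    ny, nx = int(np.ceil(depth / sy)), int(np.ceil(width / sx))

    # collect components
    comps = ["matrix"]
    for s in samples:
        for c in s.components:
            if c not in comps:
                comps.append(c)
    for extra in ("hydroxyapatite", phantom.background, holder_material):
        if extra not in comps:
            comps.append(extra)
    comps = tuple(comps)
    grid = np.zeros((len(comps), nz, ny, nx), dtype=np.float32)
    grid[comps.index(holder_material)] = 1.0

    # sample row along x, centered in its y band
    vois, slices = [], []
    y0_mm = margin + sample_diameter / 2
    x_cursor = margin + gap
    occupied: list[tuple[float, float]] = []
    for s in samples:
        w_mm = s.shape[2] * s.spacing[2]
        x_lo = x_cursor
        x_hi = x_lo + w_mm
        for a, b in occupied:
            if x_lo < b and a < x_hi:
                raise LayoutError("overlapping sample placements")
        occupied.append((x_lo, x_hi))
        iz = slice(1, 1 + s.shape[0])
        iy0 = int(round((y0_mm - s.shape[1] * s.spacing[1] / 2) / sy))
        iy = slice(iy0, iy0 + s.shape[1])
        ix0 = int(round(x_lo / sx))
        ix = slice(ix0, ix0 + s.shape[2])
        # insert only voxels inside the sample cylinder; elsewhere keep holder
        yy = (np.arange(s.shape[1]) + 0.5) * s.spacing[1] - s.shape[1] * s.spacing[1] / 2
        xx = (np.arange(s.shape[2]) + 0.5) * s.spacing[2] - w_mm / 2
        inside = (yy[:, None] ** 2 + xx[None, :] ** 2) <= (sample_diameter / 2) ** 2
        # clear the holder inside the cylinder first: a sample component may
        # coincide with the holder material (e.g. a water-filled holder)
        hold = grid[comps.index(holder_material), iz, iy, ix]
        hold[:, inside] = 0.0
        grid[comps.index(holder_material), iz, iy, ix] = hold
        for ci, c in enumerate(s.components):
            dst = grid[comps.index(c), iz, iy, ix]
            dst[:, inside] = s.grid[ci][:, inside]
            grid[comps.index(c), iz, iy, ix] = dst

        src_voi = s.voi or _default_voi(s.extent, 12.5, 0.5)
        center = (
            (1 + s.shape[0] / 2) * sz,
            y0_mm,
            x_lo + w_mm / 2,
        )
        vois.append(
            VOIGeometry(
                diameter=src_voi.diameter,
                height=src_voi.height,
                center=center,
                axis=0,
            )
        )
        slices.append((iz, iy, ix))
        x_cursor = x_hi + gap

    # phantom rods along z, in the lower y band
    rod_y = depth - margin - phantom.rod_radius
    yy = (np.arange(ny) + 0.5) * sy
    xx = (np.arange(nx) + 0.5) * sx
    rod_masks = []
    ha_idx = comps.index("hydroxyapatite")
    bg_idx = comps.index(phantom.background)
    hold_idx = comps.index(holder_material)
    rod_x0 = margin + phantom.rod_gap + phantom.rod_radius
    for k, dens in enumerate(phantom.rod_densities):
        cx = rod_x0 + k * (rod_d + phantom.rod_gap)
        in_plane = (yy[:, None] - rod_y) ** 2 + (xx[None, :] - cx) ** 2 <= phantom.rod_radius**2
        mask = np.broadcast_to(in_plane, (nz, ny, nx)).copy()
        v = phantom.ha_fraction(dens)
        # clear the holder first: the rod background may be the holder material
        grid[hold_idx][mask] = 0.0
        grid[ha_idx][mask] = v
        grid[bg_idx][mask] = grid[bg_idx][mask] + (1.0 - v)
        rod_masks.append(mask)

    vol = FractionVolume(grid=grid, spacing=(sz, sy, sx), components=comps)
    return Scene(volume=vol, rod_masks=rod_masks, vois=vois, sample_slices=slices)
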