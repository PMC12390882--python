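"""Reading and writing volumes as NIfTI with JSON metadata sidecars.

Fraction maps store one NIfTI per scene with the component axis last;
HU images store their acquisition metadata (modality, energy, dose, noise,
seed) in a ``.json`` sidecar next to the image so a round trip preserves the
full provenance of a simulation.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import FractionVolume, VOIGeometry
from .simulate import HUImage

__all__ = [
    "save_fraction_volume",
    "load_fraction_volume",
    "save_hu_image",
    "load_hu_image",
]


def _affine(spacing) -> np.ndarray:
    # grid axes are (slice, row, column); NIfTI stores column-fastest
    return np.diag([spacing[2], spacing[1], spacing[0], 1.0])


def save_fraction_volume(volume: FractionVolume, path) -> Path:
    path = Path(path)
    data = np.moveaxis(volume.grid, 0, -1).transpose(2, 1, 0, 3)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(volume.spacing))
    nib.save(img, path)
    meta = {
        "components": list(volume.components),
        "spacing": list(volume.spacing),
        "ground_truth_bvtv": volume.ground_truth_bvtv,
        "voi": None
        if volume.voi is None
        else {
            "diameter": volume.voi.diameter,
            "height": volume.voi.height,
            "center": list(volume.voi.center),
            "axis": volume.voi.axis,
        },
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_fraction_volume(path) -> FractionVolume:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    data = np.asarray(img.dataobj, dtype=np.float32).transpose(2, 1, 0, 3)
    voi = None
    if meta["voi"] is not None:
        voi = VOIGeometry(
            diameter=meta["voi"]["diameter"],
            height=meta["voi"]["height"],
            center=tuple(meta["voi"]["center"]),
            axis=meta["voi"]["axis"],
        )
    return FractionVolume(
        grid=np.moveaxis(data, -1, 0),
        spacing=tuple(meta["spacing"]),
        components=tuple(meta["components"]),
        ground_truth_bvtv=meta["ground_truth_bvtv"],
        voi=voi,
    )


def save_hu_image(image: HUImage, path) -> Path:
    path = Path(path)
    data = image.grid.transpose(2, 1, 0)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(image.spacing)), path)
    meta = {
        "spacing": list(image.spacing),
        "modality": image.modality,
        "energy_kev": image.energy_kev,
        "ctdi": image.ctdi,
        "noise_sigma": image.noise_sigma,
        "seed": image.seed,
        "kvp": image.kvp,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_hu_image(path) -> HUImage:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return HUImage(
        grid=np.asarray(img.dataobj, dtype=np.float32).transpose(2, 1, 0),
        spacing=tuple(meta["spacing"]),
        modality=meta["modality"],
        energy_kev=meta["energy_kev"],
        ctdi=meta["ctdi"],
        noise_sigma=meta["noise_sigma"],
        seed=meta["seed"],
        kvp=meta["kvp"],
    )
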