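# bvtvkit

Simulation and estimation toolkit for comparing CT-based measurements of the
trabecular **bone volume fraction** (BV/TV) — the share of a volume of
interest occupied by mineralised bone — against a high-resolution reference.

Clinically, BV/TV is estimated either by **quantitative CT** (QCT: a
single-energy scan calibrated with a hydroxyapatite phantom, converted to
volumetric bone mineral density and divided by the density of fully
mineralised tissue, 1200 mgHA/cm³) or, phantom-less, from **virtual
monochromatic images** (VMIs) reconstructed by spectral scanners
(dual-energy CT or photon-counting CT). The QCT route silently assumes the
intertrabecular space is water-like; fatty marrow, bleeding or — in ex-vivo
and post-mortem work — trapped air violate that assumption and bias the
estimate. The spectral route solves for the tissue composition directly and
should be robust to it. `bvtvkit` provides everything needed to quantify
that difference under controlled, fully synthetic conditions:

* a **material library** (water, air, 0.9 % saline, adipose surrogate,
  collagen, hydroxyapatite, and the collagen/HA bone-matrix composite) with
  energy-dependent mass-attenuation tables and the monoenergetic HU mixture
  model `HU(E) = Σᵢ ρᵢ αᵢ(E) φᵢ − Θ`;
* a **synthetic specimen generator**: cylindrical trabecular cores
  (13 mm ⌀, BV/TV 17–40 %) as thresholded Gaussian random fields, fluid
  fills with optional residual air bubbles, partial-volume resampling to
  clinical grids, and scene assembly with a six-rod HA calibration phantom
  (0–800 mgHA/cm³);
* a **CT simulator** producing VMIs and effective-energy QCT images with
  dose-dependent Gaussian noise (photon-counting and dual-energy presets);
* three **estimators**: pooled-Otsu reference segmentation, phantom-
  calibrated QCT, and the bounded weighted least-squares VMI decomposition

  solving, per fluid group, the overdetermined system of one HU equation per
  energy (default 40, 60, 80, 100 keV) plus a volume-conservation row, for
  the unknowns BV/TV, φ_fluid, φ_air ∈ [0, 1];
* the **evaluation statistics**: mean error with one-sample t-tests,
  short-term precision error (RMS of per-sample SDs over repeated
  measurements), and balanced factorial ANOVAs with Bonferroni-adjusted
  pairwise contrasts on marginal means.

## Worked example

Generate a fat-filled specimen with 5 % residual air bubbles, scan it at the
four VMI energies with the photon-counting noise preset at a low dose
(2.3 mGy), and decompose:

```python
import bvtvkit as bk

vol = bk.generate_trabecular(0.285, size=(9.0, 13.0, 13.0), spacing=0.1, seed=1)
print(f"ground-truth BV/TV in VOI: {vol.ground_truth_bvtv:.4f}")

filled = bk.fill_pores(vol, "fat", residual_air_fraction=0.05, seed=2)
clinical = bk.downsample_to_grid(filled, pixel=0.43, slice_thickness=0.6)

images = {e: bk.simulate_vmi(clinical, e, bk.NoiseModel.pct(), ctdi=2.3, seed=3)
          for e in bk.DEFAULT_ENERGIES}
est = bk.vmi_bvtv(images, clinical.voi, fluid_group="fat")
print(f"estimated BV/TV:  {est.bvtv:.4f}")
print(f"estimated fat:    {est.phi_fluid:.4f}")
print(f"estimated air:    {est.phi_air:.4f}")
```

```
ground-truth BV/TV in VOI: 0.2847
estimated BV/TV:  0.2841
estimated fat:    0.6770
estimated air:    0.0389
```

The decomposition recovers the bone fraction to well under one percentage
point at a tenth of the standard dose, and correctly attributes ~5 % of the
pore space to air. Running the same specimen through the phantom-calibrated
QCT path instead (see `bvtvkit.qct`) under-reads fat-filled samples,
over-reads saline-filled ones, and fails completely (errors below −20 BV/TV
percentage points) when the pores hold air.

The full benchmark — 16 samples, three fluids, seven scan protocols, two
repetitions, pooled-Otsu reference — is one call
(`bvtvkit.run_study(bvtvkit.StudyConfig())`) or one shell command:

```sh
bvtvkit benchmark --n-samples 16 --seed 1 --out results/
bvtvkit evaluate results/records.csv --out results/
```

which writes the per-record CSV, the accuracy/precision table and the four
factorial scenario reports (clinical fluid × measurement, photon-counting
dose × voltage, dual-energy dose, post-mortem fluid × measurement).

## Layout

| module | contents |
| --- | --- |
| `bvtvkit.materials` | material library, attenuation tables, HU mixture model |
| `bvtvkit.phantom` | specimen generator, fluid fills, resampling, scene assembly |
| `bvtvkit.simulate` | VMI / QCT image simulation, noise presets, VOI means |
| `bvtvkit.microct` | pooled-Otsu reference segmentation |
| `bvtvkit.qct` | rod averaging, HU→vBMD calibration, BV/TV conversion |
| `bvtvkit.vmi` | spectral decomposition system and bounded solver |
| `bvtvkit.evaluation` | accuracy, precision, factorial ANOVA, pairwise contrasts |
| `bvtvkit.study` | protocols, study configuration, end-to-end benchmark |
| `bvtvkit.io` | NIfTI round trips with JSON metadata sidecars |
| `bvtvkit.cli` | `bvtvkit` command-line interface |

See `docs/methods.md` for the underlying models, parameter choices and
limitations.
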