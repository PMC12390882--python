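# Methods

This note documents the models implemented in `bvtvkit`, the defaults they
ship with, and what the synthetic data can and cannot say about real
measurements.

## The HU mixture model

A CT voxel holding volume fractions φᵢ of materials with densities ρᵢ
(g/cm³) attenuates, at photon energy E, as

    HU(E) = Σᵢ ρᵢ · αᵢ(E) · φᵢ − Θ

where αᵢ(E) is the mass attenuation coefficient of material *i* divided by
that of water and scaled by 1000, and Θ = 1000 is the Hounsfield offset.
The scaling is forced by the model itself: with Θ = 1000, pure unit-density
water yields HU = 0 at every energy only if α_water ≡ 1000. Θ is in truth
scanner-specific ("approximately 1000"); it is fixed at 1000 and exposed
through `HUModelConstants`.

Trabecular bone tissue is a two-phase composite of collagen (ρ = 1.2) and
hydroxyapatite (ρ = 3.06) treated as a single "matrix" material of average
density 1.92 g/cm³. Those three densities pin down a unique volume split,
v_HA = 0.72/1.86 ≈ 0.387, hence mass fractions 0.617/0.383, and the matrix
attenuation is the mass-fraction-weighted mixture of the constituent μ/ρ
(the standard mixture rule). The split is exposed in
`matrix_composition()` and overridable, since it is an inference from the
composite density rather than a measured quantity.

### Attenuation data

Each material ships as a plain-text two-column table (keV, cm²/g) on a
17-point grid covering 30–150 keV, loaded with log-log interpolation and no
extrapolation. The tables are anchored to NIST/XCOM reference totals for
water, air, hydrogen and carbon; oxygen is recovered from the water mixture
rule, and the heavier elements (N, Na, P, S, Cl, Ca) use a standard
three-component cross-section model — exact Klein–Nishina incoherent
scattering scaled by Z/A, coherent scattering scaled by Z^2.5/A and the
photoelectric term scaled by Z⁴/A, each anchored to the oxygen
decomposition. The model reproduces published elemental values well in this
energy range (e.g. calcium at 100 keV: 0.202 cm²/g). Compound tables use
mass-weighted mixing: saline as 99.1 % water + 0.9 % NaCl, the adipose
surrogate from the ICRU-46 adipose elemental composition, collagen from a
C₁₀₂H₁₄₉N₃₁O₃₈ repeat unit, and PMMA (the sample-holder material) as
C₅H₈O₂. User-supplied tables in the same format are accepted.

Two consequences worth knowing: the air/water attenuation ratio at 60 keV
is ≈ 0.911, so an "air" voxel simulates to ≈ −998.8 HU rather than the
conventional −1000 (the mixture model, not the scanner convention, defines
the scale here); and all estimator accuracy statements in this package are
self-consistent — forward simulation and inversion share one table set, so
table inaccuracies cancel and do not inflate or mask estimator errors.

## Synthetic specimens

Samples emulate cylindrical trabecular cores: 13 mm diameter, heights drawn
uniformly from 7.8–11 mm, target BV/TV uniform in 17–40 %. Texture is a
Gaussian random field smoothed to a correlation length of 0.6 mm (a typical
trabecular strut scale) and thresholded at the quantile that achieves the
target fraction — guaranteeing the achieved BV/TV to within one voxel-count
quantum and making volumes bit-reproducible per seed. This reproduces the
two properties the estimators actually sense (a binary matrix/pore
microstructure with controlled volume fraction and strut scale); it does
not attempt plate/rod architecture, anisotropy, cortical shells or marrow
heterogeneity.

Pore space is filled with one of three marrow substitutes — air, 0.9 %
saline, or the adipose surrogate — with an optional residual-air share left
as correlated bubbles (smoothed-noise quantile over the pore voxels),
emulating gas trapped after filling. The benchmark default leaves 2 % of
the pore volume as air in liquid fills.

The measurement VOI is a cylinder of fixed 12.5 mm diameter and
sample-specific height (sample height minus a 0.5 mm margin per end),
strictly inside the 13 mm core; voxel membership is by voxel center. The
reference grid is 0.05 mm by default in the study driver — fine enough to
resolve 0.6 mm struts with negligible partial-volume error while keeping a
sixteen-sample benchmark at desk scale; the generator itself accepts any
spacing (a 0.02 mm grid mirrors micro-CT practice at ~25× the cost).

Clinical grids are produced by exact partial-volume averaging: each target
voxel's fractions are the volume-weighted mean of the source fractions over
its footprint. The target voxel count per axis is chosen so the grid tiles
the source extent exactly (the recorded spacing is the requested one
rounded to the nearest exact divisor, e.g. 0.4333 mm for 0.43 mm over
13 mm); this keeps per-voxel fractions summing to one and conserves
component volumes to floating point.

Scenes place up to four samples side by side (axes along the slice
direction) in a PMMA holder above the six calibration rods
(0, 100, 200, 400, 600, 800 mgHA/cm³; HA dispersed in water), rods running
parallel to the sample axes so every axial slice cuts all six. Rods are
rasterised by voxel center, so rod-mask voxels carry the exact nominal HA
fraction.

## Image simulation

Images are the mixture model evaluated per voxel plus i.i.d. Gaussian noise
with

    σ(CTDI, E) = f_modality · σ_ref · (E_ref / E)^γ · √(CTDI_ref / CTDI)

with σ_ref = 15 HU at 22.3 mGy and 70 keV. The dual-energy preset uses
γ = 1 and f = 1.0 (scintillator detectors amplify noise at low
reconstruction energies); the photon-counting preset uses γ = 0 and
f = 0.6 (energy-resolving detectors are more dose-efficient and
energy-flat); the QCT preset uses γ = 0, f = 1.0. These presets are the
modelling device by which the two spectral technologies differ — no
detector physics, spectra, beam hardening, scatter or spatial noise
correlation is simulated. QCT images are simulated at a single effective
energy, 65 keV for a 120 kVp protocol (the usual ≈ 55 %-of-kVp rule),
config-exposed.

## Estimators

**Reference (micro-CT-style).** A global Otsu threshold is computed per
sample from the VOI voxel values (256 histogram bins spanning the
0.1–99.9 percentile range; candidate thresholds at bin midpoints; ties to
the lower threshold), the per-sample thresholds are averaged into one
pooled threshold, and BV/TV is the fraction of VOI voxels strictly above
it. Percentile binning, the strict inequality and the tie rule are declared
choices; on noiseless high-resolution volumes the histogram is two-valued
and the reference equals the generator's ground truth exactly. The study
driver evaluates the reference through a fine (4096-bin) histogram summary
of the VOI values rather than retaining every high-resolution voxel; with
no mass near the threshold this is exact, and it is tested against the
direct path.

**Calibrated QCT.** Per-rod HU means over the slices spanned by the
sample's VOI are regressed (ordinary least squares) as
density = slope·HU + intercept; the VOI-mean HU maps through the line to a
vBMD and BV/TV = vBMD / 1200 mgHA/cm³ (constant-mineralisation assumption).
The regression direction is density-on-HU, and raw (possibly negative)
vBMD is retained — clipping to [0, 1] happens only at reporting — because
the magnitude of the air-fill failure is itself a result.

**Spectral decomposition.** For each fluid group the VOI-mean HU at the
four energies (40, 60, 80, 100 keV — the most stable combination) gives
four linear equations in the unknown fractions; volume conservation
(Σφ = 1) adds a fifth. Fat and saline groups solve for
(BV/TV, φ_fluid, φ_air); the air group nominally has three unknowns too,
but zeroing both fluids makes the fluid column duplicate the air column, so
it is posed with two (a documented divergence — the rank-deficient
three-unknown form has no unique solution). The system is solved by
bounded ([0, 1]) weighted linear least squares (`scipy.optimize.lsq_linear`,
BVLS). Energy rows carry unit weight; the conservation row, whose raw
coefficients are O(1) against energy-row norms of O(10³), is scaled by the
mean energy-row norm times a configurable factor (default 1.0) so both
kinds of information enter on the same footing. The weighting is a design
surface, recorded in the system object.

## Statistics

All BV/TV statistics are in percent. Accuracy of a measurement cell is the
mean over samples of the repetition-averaged error, with a two-sided
one-sample t-test against zero (n−1 degrees of freedom; zero-variance cells
report as degenerate). Precision follows the densitometry convention:
per-sample SD over the two repetitions (|Δ₁ − Δ₂|/√2), overall precision
error = RMS of the per-sample SDs; single-repetition cells report precision
as unavailable.

Factorial comparisons use OLS ANOVA with Type II sums of squares (identical
to Type I/III on the balanced designs produced here; unbalanced input is
rejected naming the missing cells). Significant effects are followed by
Bonferroni-adjusted pairwise contrasts on estimated marginal means using the
pooled residual variance. Assumption checks (boxplot-rule outliers at
1.5×/3× IQR, Shapiro–Wilk on residuals, Levene across cells) are attached
to every fitted model. Four scenarios are predefined: the clinical
fluid × measurement comparison at matched dose, the photon-counting
dose × voltage × fluid design, the one-way dual-energy dose comparison
(fat only, since the low-dose acquisition exists only for that group), and
the post-mortem fluid × measurement design including air. The
photon-counting dose scenario analyses repetition-level deltas (its cells
contain every repetition, doubling the residual degrees of freedom); the
other scenarios analyse per-sample means.

## Benchmark defaults

Sixteen samples, two repetitions, three fluids, and seven protocols:
calibrated QCT (120 kVp, 22.33 mGy, 0.6 mm slices), dual-energy
(80/Sn140 kVp, 0.6 mm) at 22.27 and 2.31 mGy (the low dose acquired once,
fat only), and photon-counting at 120 and 140 kVp (0.4 mm) at ≈ 22.3 and
≈ 2.3 mGy; all on 0.43 mm pixels. Every random draw derives from one study
seed through named integer substreams, so identical configurations produce
byte-identical record tables.

The dose-robustness experiment is a scaled clinical scenario: 200 samples
on a 0.15 mm generation grid, liquid fills without residual air, decomposed
under both spectral noise presets at 22.3 and 2.3 mGy against the
generator's ground truth. With the true air fraction on the boundary of the
feasible region, noise induces a small clipping bias that grows with the
noise level; this — not sampling luck — is why the dual-energy dose gap
exceeds the photon-counting one.

## Numerical choices and degenerate inputs

* Log-log interpolation inside attenuation tables; energies outside
  30–150 keV raise a range error rather than extrapolate.
* Volumes store fractions as float32; resampling contracts in float32
  (errors ~10⁻⁷ per voxel), images are computed and held in float64.
* `lsq_linear` runs with the BVLS active-set method at tol = 1e−14:
  deterministic, and exact on consistent systems to ~1e−10.
* Otsu on constant input, empty VOIs, constant rod HU and unbalanced ANOVA
  designs all raise typed errors; the rank of each decomposition system is
  checked and flagged on the estimate rather than raised.
* Generated textures use periodic boundary handling in the smoothing filter,
  so block edges carry no artificial gradient.

## What passing tests do and do not show

The synthetic data share the estimators' *measurement model* (the same
mixture forward model generates and inverts the images), so the test suite
validates the estimation machinery, the relative behaviour of the methods
(fluid sensitivity of QCT, air collapse, dose robustness of the
photon-counting preset) and the statistical pipeline — not absolute
real-scanner accuracy. Real acquisitions add beam hardening, scatter,
correlated reconstruction noise, vendor-specific VMI synthesis, partial
mineralisation variation and registration error, none of which is modelled.
Magnitudes that depend on those physics (e.g. exactly how far a fat fill
biases calibrated QCT) should be read as properties of this synthetic
world; signs and orderings are the transferable content.
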