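"""Phantom-calibrated QCT estimation."""

import numpy as np
import pytest

from bvtvkit.materials import AttenuationTable, Material, default_library
from bvtvkit.phantom import (
    CalibrationPhantomSpec,
    VOIGeometry,
    assemble_scene,
    downsample_to_grid,
    fill_pores,
    generate_trabecular,
)
from bvtvkit.qct import (
    SingularFitError,
    calibrate,
    qct_bvtv,
    rod_mean_hu,
)
from bvtvkit.simulate import HUImage, simulate_qct

PHANTOM = CalibrationPhantomSpec()


class TestRodMeanHu:
    def _setup(self, per_slice):
        grid = np.zeros((3, 4, 4))
        for z, v in enumerate(per_slice):
            grid[z] = v
        img = HUImage(grid, (1.0, 1.0, 1.0), "QCT", 65, 22.3, 0.0)
        mask = np.zeros_like(grid, dtype=bool)
        mask[:, 1:3, 1:3] = True
        voi = VOIGeometry(diameter=3.0, height=3.0, center=(1.5, 2.0, 2.0))
        return img, [mask], voi

    def test_constant_rod(self):
        img, masks, voi = self._setup([7.0, 7.0, 7.0])
        assert rod_mean_hu(img, masks, voi)[0] == pytest.approx(7.0)

    def test_slicewise_average(self):
        img, masks, voi = self._setup([10.0, 20.0, 30.0])
        assert rod_mean_hu(img, masks, voi)[0] == pytest.approx(20.0)

    def test_voi_height_restricts_slices(self):
        img, masks, _ = self._setup([10.0, 20.0, 30.0])
        narrow = VOIGeometry(diameter=3.0, height=1.0, center=(1.5, 2.0, 2.0))
        assert rod_mean_hu(img, masks, narrow)[0] == pytest.approx(20.0)

    def test_empty_mask_rejected(self):
        img, _, voi = self._setup([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            rod_mean_hu(img, [np.zeros(img.grid.shape, dtype=bool)], voi)


class TestCalibrate:
    def test_two_point_line(self):
        cal = calibrate([0.0, 800.0], [0.0, 1000.0])
        assert cal.slope == pytest.approx(1.25)
        assert cal.intercept == pytest.approx(0.0)

    def test_permutation_invariance(self):
        hu = [10.0, 200.0, 450.0, 700.0]
        dens = [0.0, 200.0, 400.0, 600.0]
        a = calibrate(hu, dens)
        order = [2, 0, 3, 1]
        b = calibrate([hu[i] for i in order], [dens[i] for i in order])
        assert (a.slope, a.intercept) == pytest.approx((b.slope, b.intercept))

    def test_constant_hu_singular(self):
        with pytest.raises(SingularFitError):
            calibrate([5.0, 5.0, 5.0], [0.0, 100.0, 200.0])

    def test_noiseless_simulated_rods_fit_to_sub_mg(self, library):
        """The forward model is affine in HA fraction, so the fit is near exact."""
        hus = []
        for c in PHANTOM.rod_densities:
            v = PHANTOM.ha_fraction(c)
            hus.append(
                1000.0
                * (
                    3.06 * v * library["hydroxyapatite"].attenuation(65.0)
                    + (1 - v) * library["water"].attenuation(65.0)
                )
                / library["water"].attenuation(65.0)
                - 1000.0
            )
        cal = calibrate(hus, PHANTOM.rod_densities)
        resid = [cal.vbmd(h) - c for h, c in zip(hus, PHANTOM.rod_densities)]
        assert np.abs(resid).max() < 0.5
        assert cal.r_squared > 1 - 1e-9


class TestQctBvtv:
    def test_vbmd_to_bvtv_conversion(self):
        cal = calibrate([0.0, 800.0], [0.0, 800.0])  # identity mapping
        img = HUImage(np.full((6, 6, 6), 600.0), (1.0,) * 3, "QCT", 65, 22.3, 0.0)
        voi = VOIGeometry(diameter=4.0, height=4.0, center=(3.0, 3.0, 3.0))
        est = qct_bvtv(img, voi, cal)
        assert est.vbmd == pytest.approx(600.0)
        assert est.bvtv == pytest.approx(0.5)

    def test_negative_raw_values_retained(self):
        cal = calibrate([0.0, 800.0], [0.0, 800.0])
        img = HUImage(np.full((6, 6, 6), -500.0), (1.0,) * 3, "QCT", 65, 22.3, 0.0)
        voi = VOIGeometry(diameter=4.0, height=4.0, center=(3.0, 3.0, 3.0))
        est = qct_bvtv(img, voi, cal)
        assert est.bvtv < 0
        assert est.bvtv_clipped == 0.0

    def test_closed_loop_consistent_mode(self):
        """With the matrix modelled as 1200 mgHA/cm3 of HA in water and a water
        fill, the QCT forward and inverse models coincide and the estimate is
        exact to floating point."""
        lib = dict(default_library())
        water, ha = lib["water"], lib["hydroxyapatite"]
        v = 1200.0 / 1000.0 / 3.06  # HA volume fraction of the consistent matrix
        rho = v * 3.06 + (1 - v) * 1.0
        mu_lin = v * 3.06 * ha.attenuation.mu_over_rho + (1 - v) * water.attenuation.mu_over_rho
        lib["matrix"] = Material(
            "matrix", rho, AttenuationTable(ha.attenuation.energies, mu_lin / rho)
        )
        vol = generate_trabecular(0.3, (8.0, 13.0, 13.0), 0.2, seed=6)
        filled = fill_pores(vol, "saline")  # placeholder components
        # replace the fluid by water for the consistent closed loop
        comps = tuple("water" if c == "saline" else c for c in filled.components)
        filled.components = comps
        ds = downsample_to_grid(filled, 0.43, 0.6)
        scene = assemble_scene([ds], holder_material="water")
        img = simulate_qct(scene.volume, 65.0, library=lib)
        rods = rod_mean_hu(img, scene.rod_masks, scene.vois[0])
        cal = calibrate(rods, PHANTOM.rod_densities)
        est = qct_bvtv(img, scene.vois[0], cal)
        mask = scene.vois[0].mask(scene.volume.shape, scene.volume.spacing)
        truth = float(scene.volume.component("matrix")[mask].astype(np.float64).mean())
        assert est.bvtv == pytest.approx(truth, abs=1e-6)

    def test_fluid_bias_signs_in_realistic_mode(self):
        """Water-based calibration under-reads fat fills, over-reads saline and
        collapses with air."""
        vol = generate_trabecular(0.3, (8.0, 13.0, 13.0), 0.2, seed=7)
        estimates = {}
        for fluid in ("fat", "saline", "air"):
            ds = downsample_to_grid(fill_pores(vol, fluid), 0.43, 0.6)
            scene = assemble_scene([ds])
            img = simulate_qct(scene.volume, 65.0)
            rods = rod_mean_hu(img, scene.rod_masks, scene.vois[0])
            cal = calibrate(rods, PHANTOM.rod_densities)
            mask = scene.vois[0].mask(scene.volume.shape, scene.volume.spacing)
            truth = float(scene.volume.component("matrix")[mask].mean())
            estimates[fluid] = qct_bvtv(img, scene.vois[0], cal).bvtv - truth
        assert estimates["fat"] < 0 < estimates["saline"]
        assert estimates["air"] < -0.20
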