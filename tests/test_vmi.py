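"""Phantom-less spectral decomposition: system assembly and bounded solving."""

import numpy as np
import pytest

from bvtvkit.materials import default_library, hu_of_mixture
from bvtvkit.phantom import downsample_to_grid, fill_pores, generate_trabecular
from bvtvkit.simulate import simulate_vmi
from bvtvkit.vmi import (
    DEFAULT_ENERGIES,
    DecompositionSystem,
    SpectralMeasurement,
    build_system,
    solve,
    vmi_bvtv,
)


def forward_measurement(fractions, energies=DEFAULT_ENERGIES):
    """Noiseless VOI-mean HU for given component fractions."""
    return SpectralMeasurement(
        energies=tuple(energies),
        mean_hu=tuple(hu_of_mixture(fractions, e) for e in energies),
    )


def grid_search_objective(system, step=1e-3, coarse=1e-2):
    """Independent minimiser: dense grid refined around the coarse optimum.

    The objective is convex, so refining around the coarse grid optimum
    cannot miss the global minimum by more than a coarse cell.
    """
    sw = np.sqrt(system.weights)
    aw = system.matrix * sw[:, None]
    bw = system.rhs * sw

    def best_on(axes):
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, len(axes))
        r = pts @ aw.T - bw
        obj = (r**2).sum(axis=1)
        k = int(np.argmin(obj))
        return pts[k], float(obj[k])

    n = system.matrix.shape[1]
    x0, _ = best_on([np.arange(0, 1 + coarse / 2, coarse)] * n)
    axes = [
        np.clip(np.arange(x0[i] - 2 * coarse, x0[i] + 2 * coarse + step / 2, step), 0, 1)
        for i in range(n)
    ]
    _, obj = best_on(axes)
    return obj


class TestBuildSystem:
    def test_saline_group_is_five_by_three(self):
        sys_ = build_system(forward_measurement({"matrix": 0.3, "saline": 0.7}), "saline")
        assert sys_.matrix.shape == (5, 3)
        assert sys_.unknowns == ("bvtv", "saline", "air")
        assert sys_.bounds == (0.0, 1.0)

    def test_air_group_is_five_by_two(self):
        sys_ = build_system(forward_measurement({"matrix": 0.3, "air": 0.7}), "air")
        assert sys_.matrix.shape == (5, 2)
        assert sys_.unknowns == ("bvtv", "air")

    def test_conservation_row_rhs_is_one(self):
        for fracs in ({"matrix": 0.2, "fat": 0.8}, {"matrix": 0.4, "fat": 0.1}):
            sys_ = build_system(forward_measurement(fracs), "fat")
            assert sys_.rhs[-1] == 1.0
            assert np.all(sys_.matrix[-1] == 1.0)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="fluid group"):
            build_system(forward_measurement({"matrix": 0.3, "fat": 0.7}), "plasma")


class TestSolve:
    def test_recovers_consistent_system(self):
        meas = forward_measurement({"matrix": 0.3, "fat": 0.7})
        est = solve(build_system(meas, "fat"))
        assert est.bvtv == pytest.approx(0.3, abs=1e-8)
        assert est.phi_fluid == pytest.approx(0.7, abs=1e-8)
        assert est.phi_air == pytest.approx(0.0, abs=1e-8)

    def test_matrix_fat_fixture_recovery(self):
        """The same 30/70 mixture used as the mixture-model worked example."""
        fixture_hu = {40.0: 667.829, 60.0: 343.808, 80.0: 248.536, 100.0: 212.462}
        meas = SpectralMeasurement(
            energies=tuple(sorted(fixture_hu)),
            mean_hu=tuple(fixture_hu[e] for e in sorted(fixture_hu)),
        )
        est = solve(build_system(meas, "fat"))
        assert est.bvtv == pytest.approx(0.3, abs=1e-5)
        assert est.phi_fluid == pytest.approx(0.7, abs=1e-5)

    def test_negative_direction_clips_at_bound_like_grid_search(self):
        """Data consistent with a negative phi_air: the solution pins the bound
        and matches the independent grid search."""
        sys_ = build_system(forward_measurement({"matrix": 0.3, "fat": 0.7}), "fat")
        x_out = np.array([0.32, 0.76, -0.08])  # infeasible "truth"
        sys_.rhs = sys_.matrix @ x_out
        sys_.rhs[-1] = 1.0  # conservation row keeps its definition
        est = solve(sys_)
        assert est.phi_air == pytest.approx(0.0, abs=1e-9)
        assert "air" in est.active_bounds
        sw = np.sqrt(sys_.weights)
        x = np.array([est.bvtv, est.phi_fluid, est.phi_air])
        obj = float((((sys_.matrix @ x - sys_.rhs) * sw) ** 2).sum())
        assert obj <= grid_search_objective(sys_) + 1e-9

    def test_duplicate_row_equals_doubled_weight(self):
        meas = forward_measurement({"matrix": 0.25, "saline": 0.7, "air": 0.05})
        base = build_system(meas, "saline")
        dup = DecompositionSystem(
            matrix=np.vstack([base.matrix, base.matrix[0]]),
            rhs=np.append(base.rhs, base.rhs[0]),
            unknowns=base.unknowns,
            weights=np.append(base.weights, 1.0),
        )
        wtd = DecompositionSystem(
            matrix=base.matrix.copy(),
            rhs=base.rhs.copy(),
            unknowns=base.unknowns,
            weights=base.weights.copy(),
        )
        wtd.weights[0] = 2.0
        a, b = solve(dup), solve(wtd)
        assert a.bvtv == pytest.approx(b.bvtv, abs=1e-10)
        assert a.phi_fluid == pytest.approx(b.phi_fluid, abs=1e-10)
        assert a.phi_air == pytest.approx(b.phi_air, abs=1e-10)

    def test_full_column_rank_at_default_energies(self):
        for group, fracs in (
            ("fat", {"matrix": 0.3, "fat": 0.7}),
            ("saline", {"matrix": 0.3, "saline": 0.7}),
            ("air", {"matrix": 0.3, "air": 0.7}),
        ):
            sys_ = build_system(forward_measurement(fracs), group)
            assert np.linalg.matrix_rank(sys_.matrix) == len(sys_.unknowns)
            assert not solve(sys_).rank_deficient

    @pytest.mark.parametrize("group", ["fat", "saline", "air"])
    def test_interior_ground_truth_recovery(self, group):
        """Noiseless identifiability on random interior compositions."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            if group == "air":
                bvtv = rng.uniform(0.05, 0.95)
                fracs = {"matrix": bvtv, "air": 1 - bvtv}
                truth = (bvtv, 0.0, 1 - bvtv)
            else:
                parts = rng.dirichlet([2, 2, 1])
                fracs = {"matrix": parts[0], group: parts[1], "air": parts[2]}
                truth = tuple(parts)
            est = solve(build_system(forward_measurement(fracs), group))
            assert est.bvtv == pytest.approx(truth[0], abs=1e-6)
            assert est.phi_air == pytest.approx(truth[2], abs=1e-6)


class TestVmiBvtv:
    def test_noiseless_saline_sample_recovers_ground_truth(self, small_sample):
        ds = downsample_to_grid(fill_pores(small_sample, "saline"), 0.43, 0.6)
        imgs = {e: simulate_vmi(ds, e) for e in DEFAULT_ENERGIES}
        est = vmi_bvtv(imgs, ds.voi, "saline")
        truth = ds.mean_fraction_in_voi("matrix")
        assert est.bvtv == pytest.approx(truth, abs=0.002)

    def test_residual_air_is_attributed_to_air(self, small_sample):
        ds = downsample_to_grid(
            fill_pores(small_sample, "saline", residual_air_fraction=0.05, seed=3),
            0.43,
            0.6,
        )
        imgs = {e: simulate_vmi(ds, e) for e in DEFAULT_ENERGIES}
        est = vmi_bvtv(imgs, ds.voi, "saline")
        expected_air = 0.05 * (1 - est.bvtv)
        assert est.phi_air == pytest.approx(expected_air, abs=0.02)

    def test_grid_mismatch_rejected(self, small_sample):
        ds1 = downsample_to_grid(fill_pores(small_sample, "fat"), 0.43, 0.6)
        ds2 = downsample_to_grid(fill_pores(small_sample, "fat"), 0.43, 0.4)
        imgs = [simulate_vmi(ds1, 40.0), simulate_vmi(ds2, 80.0)]
        with pytest.raises(ValueError, match="share grid"):
            vmi_bvtv(imgs, ds1.voi, "fat")
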