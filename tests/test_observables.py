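import math

import numpy as np
import pytest

from cgsterol.observables import (
    MSDSeries,
    area_per_lipid,
    bilayer_thickness,
    bond_order_parameters,
    compare_groups,
    fit_diffusion,
    lateral_msd,
    sterol_tilt,
)
from cgsterol.templates import Bond
from cgsterol.trajectory import SiteCatalog, Trajectory


def _point_trajectory(positions, box=500.0, dt=100.0, species="CHOL", site="ROH"):
    """Trajectory of single-site molecules from positions (F, M, 3)."""
    positions = np.asarray(positions, dtype=float)
    F, M, _ = positions.shape
    cat = SiteCatalog(
        molecule_ids=np.arange(M),
        species=np.full(M, species),
        site_names=np.full(M, site),
    )
    return Trajectory(
        times=np.arange(F) * dt,
        positions=positions,
        boxes=np.full((F, 3), box),
        catalog=cat,
    )


def _bond_trajectory(vectors, species="POPC"):
    """One POPC tail bond (C1A->D2A) per molecule from vectors (F, M, 3)."""
    vectors = np.asarray(vectors, dtype=float)
    F, M, _ = vectors.shape
    cat = SiteCatalog(
        molecule_ids=np.repeat(np.arange(M), 2),
        species=np.full(2 * M, species),
        site_names=np.tile(["C1A", "D2A"], M),
    )
    pos = np.zeros((F, 2 * M, 3))
    pos[:, 0::2, :] = 10.0
    pos[:, 1::2, :] = 10.0 + vectors
    return Trajectory(
        times=np.arange(F, dtype=float) + 1.0,
        positions=pos,
        boxes=np.full((F, 3), 100.0),
        catalog=cat,
    )


BOND = Bond("POPC", "sn2", 1, "C1A", "D2A")


class TestAreaPerLipid:
    def test_two_lipids_per_leaflet_in_ten_angstrom_box(self):
        traj = _point_trajectory(np.zeros((1, 4, 3)), box=10.0)
        res = area_per_lipid(traj, n_lipids=4, convention="per_leaflet")
        assert res.mean == pytest.approx(50.0)
        assert area_per_lipid(traj, 4, "total").mean == pytest.approx(25.0)

    def test_constant_box_has_zero_sd(self):
        traj = _point_trajectory(np.zeros((100, 4, 3)), box=25.0)
        assert area_per_lipid(traj, 4).sd == 0.0

    def test_zero_lipids_rejected(self):
        traj = _point_trajectory(np.zeros((1, 4, 3)))
        with pytest.raises(ValueError):
            area_per_lipid(traj, 0)


class TestThickness:
    def _phosphate_traj(self, z_up, z_lo, shift=0.0):
        F = 5
        pos = np.zeros((F, 4, 3))
        pos[:, :2, 2] = z_up + shift
        pos[:, 2:, 2] = z_lo + shift
        cat = SiteCatalog(
            molecule_ids=np.arange(4),
            species=np.full(4, "POPC"),
            site_names=np.full(4, "PO4"),
        )
        return Trajectory(
            times=np.arange(F, dtype=float),
            positions=pos,
            boxes=np.full((F, 3), 60.0),
            catalog=cat,
        )

    def test_planes_at_plus_minus_21p5_give_43(self):
        assert bilayer_thickness(
            self._phosphate_traj(21.5, -21.5)
        ).mean == pytest.approx(43.0)

    def test_invariant_under_z_shift(self):
        a = bilayer_thickness(self._phosphate_traj(21.5, -21.5)).mean
        b = bilayer_thickness(self._phosphate_traj(21.5, -21.5, shift=55.0)).mean
        assert a == pytest.approx(b)

    def test_missing_phosphates_rejected(self):
        traj = _point_trajectory(np.zeros((1, 4, 3)))
        with pytest.raises(ValueError):
            bilayer_thickness(traj)

    def test_recovery_on_synthetic_membrane(self, small_traj, small_gt):
        res = bilayer_thickness(small_traj)
        assert res.mean == pytest.approx(small_gt.thickness, abs=0.5)


class TestLateralMSD:
    def test_static_positions_give_zero(self):
        traj = _point_trajectory(np.ones((20, 3, 3)) * 7.0)
        msd = lateral_msd(traj, "CHOL")
        np.testing.assert_allclose(msd.msd, 0.0, atol=1e-9)

    def test_uniform_drift_is_ballistic(self):
        v = 0.03  # Å/ps
        t = np.arange(50.0) * 100.0
        pos = np.zeros((50, 1, 3))
        pos[:, 0, 0] = v * t
        traj = _point_trajectory(pos, box=1e4)
        msd = lateral_msd(traj, "CHOL", max_lag_fraction=0.5)
        np.testing.assert_allclose(msd.msd, (v * msd.lag_ps) ** 2, rtol=1e-9)

    def test_origin_average_equals_single_origin_for_linear_motion(self):
        # deterministic linear motion: MSD(τ) from any origin is (vτ)²
        v = 0.05
        t = np.arange(40.0)
        pos = np.zeros((40, 1, 3))
        pos[:, 0, 1] = v * t
        traj = _point_trajectory(pos, box=1e4, dt=1.0)
        msd = lateral_msd(traj, "CHOL", max_lag_fraction=0.5)
        single_origin = (v * msd.lag_ps) ** 2
        np.testing.assert_allclose(msd.msd, single_origin, rtol=1e-9)

    def test_brownian_ensemble_recovers_slope_4d(self, rng):
        D = 0.8  # Å^2/ns
        dt_ps, F, M = 100.0, 1500, 400
        steps = rng.normal(0.0, math.sqrt(2 * D * dt_ps / 1000), (F, M, 2))
        steps[0] = 0
        pos = np.zeros((F, M, 3))
        pos[:, :, :2] = np.cumsum(steps, axis=0)
        traj = _point_trajectory(pos, box=1e5, dt=dt_ps)
        msd = lateral_msd(traj, "CHOL", max_lag_fraction=0.05)
        fit = fit_diffusion(msd)
        assert fit.D == pytest.approx(D, rel=0.05)

    def test_com_removal_cancels_collective_drift(self, rng):
        F, M = 200, 20
        drift = np.cumsum(rng.normal(0, 0.5, (F, 1, 2)), axis=0)
        pos = np.zeros((F, M, 3))
        pos[:, : M // 2, 2] = 10.0
        pos[:, M // 2 :, 2] = -10.0
        pos[:, :, :2] = drift  # identical drift, no relative motion
        traj = _point_trajectory(pos, box=1e5)
        msd = lateral_msd(traj, "CHOL", remove_com=True)
        np.testing.assert_allclose(msd.msd, 0.0, atol=1e-9)

    def test_absent_species_rejected(self):
        traj = _point_trajectory(np.zeros((5, 2, 3)))
        with pytest.raises(ValueError):
            lateral_msd(traj, "POPC")

    def test_unwrapping_across_periodic_boundary(self):
        # molecule crossing the box edge must not register a jump
        L = 30.0
        x = np.array([29.0, 29.6, 0.2, 0.8])  # wrapped drift of +0.6/frame
        pos = np.zeros((4, 1, 3))
        pos[:, 0, 0] = x
        traj = _point_trajectory(pos, box=L, dt=1.0)
        msd = lateral_msd(traj, "CHOL", max_lag_fraction=1.0)
        np.testing.assert_allclose(
            msd.msd, (0.6 * msd.lag_ps) ** 2, rtol=1e-9
        )


class TestFitDiffusion:
    def test_exact_line_gives_unit_diffusion(self):
        lag_ps = np.arange(0.0, 101.0) * 10.0
        msd = MSDSeries(
            lag_ps=lag_ps, msd=4.0 * lag_ps / 1000.0, species="x", n_molecules=1
        )
        fit = fit_diffusion(msd)
        assert fit.D == pytest.approx(1.0, rel=1e-12)  # slope 4 Å^2/ns
        assert fit.D_cm2_per_s == pytest.approx(1e-7, rel=1e-12)

    def test_noisy_line_within_three_standard_errors(self, rng):
        lag_ps = np.arange(0.0, 201.0) * 10.0
        noise = rng.normal(0, 0.5, len(lag_ps))
        msd = MSDSeries(
            lag_ps=lag_ps,
            msd=np.abs(4.0 * lag_ps / 1000.0 + noise),
            species="x",
            n_molecules=1,
        )
        fit = fit_diffusion(msd)
        assert abs(fit.D - 1.0) < 3 * fit.D_se

    def test_degenerate_window_rejected(self):
        msd = MSDSeries(
            lag_ps=np.array([0.0, 1.0, 2.0]),
            msd=np.array([0.0, 1.0, 2.0]),
            species="x",
            n_molecules=1,
        )
        with pytest.raises(ValueError):
            fit_diffusion(msd, window=(0.9, 0.95))
        with pytest.raises(ValueError):
            fit_diffusion(msd, window=(0.8, 0.2))


class TestSterolTilt:
    def _sterol_traj(self, axis):
        axis = np.asarray(axis, dtype=float)
        cat = SiteCatalog(
            molecule_ids=np.array([0, 0]),
            species=np.array(["7KC", "7KC"]),
            site_names=np.array(["K5", "KOH"]),
        )
        pos = np.zeros((1, 2, 3))
        pos[0, 0] = (10, 10, 10)
        pos[0, 1] = pos[0, 0] + axis
        return Trajectory(
            times=np.array([0.0]),
            positions=pos,
            boxes=np.full((1, 3), 50.0),
            catalog=cat,
        )

    def test_axis_along_normal_is_zero_tilt(self):
        res = sterol_tilt(self._sterol_traj([0, 0, 9.0]), "7KC", ("K5", "KOH"))
        assert res.mean_deg == pytest.approx(0.0, abs=1e-9)

    def test_axis_in_plane_is_ninety(self):
        res = sterol_tilt(self._sterol_traj([9.0, 0, 0]), "7KC", ("K5", "KOH"))
        assert res.mean_deg == pytest.approx(90.0)

    def test_leaflet_symmetric_folding(self):
        down = sterol_tilt(self._sterol_traj([0, 0, -9.0]), "7KC", ("K5", "KOH"))
        assert down.mean_deg == pytest.approx(0.0, abs=1e-9)

    def test_zero_length_vector_rejected(self):
        with pytest.raises(ValueError):
            sterol_tilt(self._sterol_traj([0, 0, 0]), "7KC", ("K5", "KOH"))

    def test_density_normalized(self, small_traj):
        res = sterol_tilt(small_traj, "CHOL", ("R5", "ROH"))
        assert np.sum(res.density) * res.bin_width == pytest.approx(1.0, abs=1e-6)

    def test_histogram_matches_sampling_density(self, small_traj, small_gt):
        from scipy.integrate import quad

        res = sterol_tilt(small_traj, "7KC", ("K5", "KOH"), bin_width=5.0)
        mode, kappa = small_gt.tilt["7KC"]
        t0 = math.radians(mode)

        def dens(theta):
            return math.sin(theta) * math.exp(kappa * (math.cos(theta - t0) - 1))

        z = quad(dens, 0, math.pi / 2)[0]
        for center, d in zip(res.bin_centers, res.density):
            lo = math.radians(center - 2.5)
            hi = math.radians(center + 2.5)
            expected = quad(dens, lo, hi)[0] / z / 5.0  # per degree
            # multinomial error at n samples
            n = res.n_samples
            se = math.sqrt(max(expected * 5.0 * (1 - expected * 5.0), 1e-12) / n) / 5.0
            assert abs(d - expected) < 5 * se + 1e-3


class TestOrderParameters:
    def test_bonds_along_normal(self):
        traj = _bond_trajectory(np.tile([0.0, 0.0, 4.7], (3, 5, 1)))
        res = bond_order_parameters(traj, [BOND])[0]
        assert res.standard_P2 == pytest.approx(1.0)
        assert res.as_printed == pytest.approx(-1.0)

    def test_magic_angle_is_zero(self):
        u = math.sqrt(1.0 / 3.0)
        s = math.sqrt(1.0 - u * u)
        traj = _bond_trajectory(np.tile([4.7 * s, 0.0, 4.7 * u], (2, 4, 1)))
        res = bond_order_parameters(traj, [BOND])[0]
        assert res.standard_P2 == pytest.approx(0.0, abs=1e-12)
        assert res.as_printed == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_orientations_average_to_zero(self, rng):
        n_f, n_m = 100, 200
        v = rng.normal(size=(n_f, n_m, 3))
        res = bond_order_parameters(_bond_trajectory(v), [BOND])[0]
        se = 0.45 / math.sqrt(n_f * n_m)
        assert abs(res.standard_P2) < 5 * se

    def test_conventions_are_exact_negatives(self, small_traj):
        for res in bond_order_parameters(small_traj):
            assert res.value("as_printed") == -res.value("standard_P2")
            assert abs(res.standard_P2) <= 1.0

    def test_missing_bond_site_rejected(self, small_traj):
        with pytest.raises(ValueError):
            bond_order_parameters(
                small_traj, [Bond("POPC", "sn2", 9, "C1A", "NOPE")]
            )


class TestCompareGroups:
    def test_identical_constant_samples(self):
        res = compare_groups([3.0, 3.0, 3.0], [3.0, 3.0])
        assert (res.t, res.p) == (0.0, 1.0)
        assert not res.significant

    def test_matches_pooled_t_closed_form(self):
        a = [1.1, 2.3, 3.0]
        b = [2.0, 4.1, 5.2]
        na, nb = 3, 3
        ma, mb = sum(a) / na, sum(b) / nb
        sa2 = sum((x - ma) ** 2 for x in a) / (na - 1)
        sb2 = sum((x - mb) ** 2 for x in b) / (nb - 1)
        sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
        t_expected = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
        res = compare_groups(a, b)
        assert res.t == pytest.approx(t_expected, abs=1e-10)

    def test_distinct_constants_are_significant(self):
        res = compare_groups([1.0, 1.0], [2.0, 2.0])
        assert res.p == 0.0 and res.significant

    def test_singleton_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
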