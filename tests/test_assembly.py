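"""Geometry primitives, SASA quadrature, and the composite assembly report."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spidrokit import assembly, synthetic
from spidrokit.assembly import (AnalysisConfig, Trajectory, analyze,
                                center_of_mass, com_distance, endpoint_delta,
                                fold_change, kabsch_superpose, percent_change,
                                radius_of_gyration, rmsf, shrake_rupley_sasa)
from spidrokit.errors import ValidationError


def two_chain_traj(coords, times=None):
    """Helper: wrap raw coordinates as a two-chain trajectory."""
    coords = np.asarray(coords, dtype=float)
    n_beads = coords.shape[1]
    half = n_beads // 2
    return Trajectory(
        coords=coords,
        times=np.arange(coords.shape[0], dtype=float) if times is None
        else times,
        chain_ids=np.array(["A"] * half + ["B"] * (n_beads - half)),
        residue_index=np.arange(n_beads),
        masses=np.full(n_beads, 72.0),
        radii=np.full(n_beads, 0.235))


class TestCenterOfMassAndComd:
    def test_single_bead(self):
        assert np.allclose(center_of_mass([[1, 2, 3]], [5.0]), [1, 2, 3])

    def test_equal_mass_midpoint(self):
        com = center_of_mass([[0, 0, 0], [2, 0, 0]], [1.0, 1.0])
        assert np.allclose(com, [1, 0, 0])

    def test_weighted_mean(self):
        com = center_of_mass([[0, 0, 0], [4, 0, 0]], [1.0, 3.0])
        assert com[0] == pytest.approx(3.0)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValidationError):
            center_of_mass([[0, 0, 0]], [0.0])

    def test_3_4_5_distance(self):
        coords = np.array([[0, 0, 0], [3, 4, 0]], dtype=float)
        masses = np.ones(2)
        d = com_distance(coords, masses, np.array([True, False]),
                         np.array([False, True]))
        assert d == pytest.approx(5.0)

    def test_superposed_chains_distance_zero(self):
        coords = np.array([[1, 1, 1], [1, 1, 1]], dtype=float)
        d = com_distance(coords, np.ones(2), np.array([True, False]),
                         np.array([False, True]))
        assert d == 0.0


class TestRadiusOfGyration:
    def test_single_bead_zero(self):
        assert radius_of_gyration([[3, 2, 1]], [1.0]) == 0.0

    def test_two_equal_masses_half_separation(self):
        d = 1.8
        rg = radius_of_gyration([[0, 0, 0], [d, 0, 0]], [2.0, 2.0])
        assert rg == pytest.approx(d / 2, abs=1e-12)

    def test_unit_cube_corners(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                            for z in (0, 1)], dtype=float)
        rg = radius_of_gyration(corners, np.ones(8))
        assert rg == pytest.approx(np.sqrt(3) / 2, abs=1e-12)


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert np.allclose(rot, np.eye(3), atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_recovered(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        shift = np.array([1.0, -2.0, 0.5])
        rot, trans, rmsd = kabsch_superpose(pts + shift, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(pts + shift @ np.eye(3), pts + shift)
        assert np.allclose((pts + shift) @ rot.T + trans, pts, atol=1e-10)

    def test_known_90_degree_rotation_recovered(self):
        rot_true = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        pts = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]],
                       dtype=float)
        mobile = pts @ rot_true.T
        rot, trans, rmsd = kabsch_superpose(mobile, pts)
        assert np.allclose(rot @ rot_true, np.eye(3), atol=1e-8)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        rot, _, _ = kabsch_superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_agrees_with_scipy_align_vectors(self):
        """Independent cross-check of the optimal rotation."""
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(12, 3))
        mobile = ref @ Rotation.random(
            random_state=4).as_matrix().T + rng.normal(scale=0.01,
                                                       size=(12, 3))
        rot, _, _ = kabsch_superpose(mobile, ref)
        ref_c = ref - ref.mean(axis=0)
        mob_c = mobile - mobile.mean(axis=0)
        scipy_rot, _ = Rotation.align_vectors(ref_c, mob_c)
        assert np.allclose(rot, scipy_rot.as_matrix(), atol=1e-6)

    def test_collinear_points_warn(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.warns(UserWarning, match="collinear"):
            kabsch_superpose(line, line)


class TestRigidInvariance:
    """Rg, COMD and superposed RMSD/RMSF ignore global rigid motion."""

    @staticmethod
    def random_rigid(rng):
        rot = Rotation.random(random_state=rng).as_matrix()
        trans = rng.normal(scale=5.0, size=3)
        return rot, trans

    def test_rg_and_comd_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(20, 3))
        masses = rng.uniform(1, 3, size=20)
        mask_a = np.arange(20) < 10
        rot, trans = self.random_rigid(rng)
        moved = coords @ rot.T + trans
        assert radius_of_gyration(moved, masses) == pytest.approx(
            radius_of_gyration(coords, masses))
        assert com_distance(moved, masses, mask_a, ~mask_a) == pytest.approx(
            com_distance(coords, masses, mask_a, ~mask_a))

    def test_rmsf_zero_for_static_trajectory(self):
        base = np.random.default_rng(6).normal(size=(10, 3))
        traj = two_chain_traj(np.stack([base] * 4))
        _, fluct = rmsf(traj)
        assert np.allclose(fluct, 0.0, atol=1e-10)

    def test_rmsf_zero_for_rigid_body_motion_with_superposition(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(10, 3))
        frames = [base]
        for _ in range(5):
            rot, trans = self.random_rigid(rng)
            frames.append(base @ rot.T + trans)
        traj = two_chain_traj(np.stack(frames))
        _, fluct = rmsf(traj, superpose=True)
        assert np.allclose(fluct, 0.0, atol=1e-8)

    def test_rmsf_two_frame_alternation(self):
        """A site alternating +-d/2 about its mean has RMSF d/2."""
        d = 0.6
        base = np.zeros((4, 3))
        base[:, 0] = [0.0, 5.0, 10.0, 15.0]
        up = base.copy()
        up[1, 0] += d / 2
        down = base.copy()
        down[1, 0] -= d / 2
        traj = two_chain_traj(np.stack([up, down]))
        _, fluct = rmsf(traj, superpose=False)
        assert fluct[1] == pytest.approx(d / 2 * 10, abs=1e-9)  # Angstrom
        assert np.allclose(np.delete(fluct, 1), 0.0, atol=1e-9)

    def test_single_frame_rejected(self):
        traj = two_chain_traj(np.zeros((1, 4, 3)) + np.arange(4)[:, None])
        with pytest.raises(ValidationError):
            rmsf(traj)


class TestShrakeRupley:
    def test_isolated_sphere_within_one_percent(self):
        r, probe = 0.235, 0.14
        sasa = shrake_rupley_sasa(np.zeros((1, 3)), np.array([r]), probe, 960)
        analytic = 4 * np.pi * (r + probe) ** 2
        assert abs(sasa - analytic) / analytic < 0.01

    def test_distant_spheres_additive(self):
        r, probe = 0.235, 0.14
        single = shrake_rupley_sasa(np.zeros((1, 3)), np.array([r]), probe,
                                    960)
        coords = np.array([[0, 0, 0], [5.0, 0, 0]])
        double = shrake_rupley_sasa(coords, np.array([r, r]), probe, 960)
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_buried_bead_contributes_nothing(self):
        coords = np.array([[0, 0, 0], [0.05, 0, 0]])
        radii = np.array([1.0, 0.1])
        per_bead = shrake_rupley_sasa(coords, radii, 0.14, 480, per_bead=True)
        assert per_bead[1] == 0.0

    def test_quadrature_converges(self):
        r, probe = 0.3, 0.14
        analytic = 4 * np.pi * (r + probe) ** 2
        errors = [abs(shrake_rupley_sasa(np.zeros((1, 3)), np.array([r]),
                                         probe, n) - analytic)
                  for n in (60, 240, 960)]
        assert errors[2] <= errors[0]
        assert errors[2] / analytic < 0.01

    def test_agrees_with_biotite_on_random_cluster(self):
        """Independent Shrake-Rupley implementation as oracle."""
        import biotite.structure as struc

        rng = np.random.default_rng(8)
        n = 12
        coords_nm = rng.normal(scale=0.4, size=(n, 3))
        radii_nm = np.full(n, 0.235)
        ours = shrake_rupley_sasa(coords_nm, radii_nm, 0.14, 960)

        atoms = struc.AtomArray(n)
        atoms.coord = coords_nm * 10.0  # Angstrom
        atoms.chain_id[:] = "A"
        atoms.res_id[:] = np.arange(1, n + 1)
        atoms.res_name[:] = "BEA"
        atoms.atom_name[:] = "C"
        atoms.element[:] = "C"
        theirs_a2 = struc.sasa(atoms, probe_radius=1.4, point_number=960,
                               vdw_radii=np.full(n, 2.35)).sum()
        assert ours == pytest.approx(theirs_a2 / 100.0, rel=0.02)

    def test_invalid_probe_and_points(self):
        with pytest.raises(ValidationError):
            shrake_rupley_sasa(np.zeros((1, 3)), np.array([0.2]), -1.0, 960)
        with pytest.raises(ValidationError):
            shrake_rupley_sasa(np.zeros((1, 3)), np.array([0.2]), 0.14, 8)


class TestSummaryHelpers:
    def test_percent_change_flat(self):
        assert percent_change([10, 10]) == 0.0

    def test_percent_change_requires_nonzero_start(self):
        with pytest.raises(ValidationError):
            percent_change([0.0, 1.0])

    def test_endpoint_delta_sign_convention(self):
        assert endpoint_delta([14.2, 13.46]) == pytest.approx(0.74)
        assert endpoint_delta([1.0, 2.0]) == pytest.approx(-1.0)

    def test_fold_change(self):
        assert fold_change([0.047, 0.99]) == pytest.approx(21.0638, abs=1e-3)


class TestAnalyze:
    def test_static_trajectory_no_assembly(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(12, 3))
        base[:6] -= [3, 0, 0]
        base[6:] += [3, 0, 0]
        traj = two_chain_traj(np.stack([base] * 5))
        metrics = analyze(traj, AnalysisConfig(sasa_points=60))
        assert not metrics.verdict
        assert metrics.deltas["rg_delta"] == pytest.approx(0.0)
        assert metrics.deltas["sasa_pct_reduction"] == pytest.approx(0.0)
        assert metrics.deltas["comd_delta"] == pytest.approx(0.0)

    def test_series_lengths_match_frames(self, jittered_traj):
        _, traj, _ = jittered_traj
        metrics = analyze(traj, AnalysisConfig(sasa_points=60))
        for series in (metrics.rg_series, metrics.sasa_series,
                       metrics.comd_series, metrics.rmsd_series):
            assert len(series) == traj.n_frames

    def test_sasa_reduction_consistent_with_series(self, jittered_traj):
        _, traj, _ = jittered_traj
        metrics = analyze(traj, AnalysisConfig(sasa_points=60))
        expected = 100 * (metrics.sasa_series[0] - metrics.sasa_series[-1]) \
            / metrics.sasa_series[0]
        assert metrics.deltas["sasa_pct_reduction"] == pytest.approx(expected)

    def test_missing_chain_rejected(self):
        traj = two_chain_traj(np.random.default_rng(10).normal(size=(3, 6, 3)))
        with pytest.raises(ValidationError):
            analyze(traj, AnalysisConfig(chain_b="Z", sasa_points=60))


class TestTrajectoryInvariants:
    def test_times_must_increase(self):
        with pytest.raises(ValidationError):
            two_chain_traj(np.zeros((2, 4, 3)), times=np.array([1.0, 1.0]))

    def test_nonfinite_coordinates_rejected(self):
        coords = np.zeros((2, 4, 3))
        coords[1, 2, 0] = np.nan
        with pytest.raises(ValidationError):
            two_chain_traj(coords)

    def test_positive_masses_and_radii_required(self):
        coords = np.zeros((2, 2, 3))
        with pytest.raises(ValidationError):
            Trajectory(coords=coords, times=[0.0, 1.0],
                       chain_ids=np.array(["A", "B"]),
                       residue_index=np.array([1, 1]),
                       masses=np.array([1.0, -1.0]),
                       radii=np.array([0.2, 0.2]))
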