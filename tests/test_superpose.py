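"""Kabsch superposition, RMSD and RMSF against independent oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helpers import quaternion_grid_rmsd
from thermofluct.superpose import (
    apply_transform,
    kabsch_superpose,
    rmsf,
    trajectory_rmsd,
)
from thermofluct.core import Trajectory
from thermofluct.synthetic import FluctuationSpec, make_reference_structure, make_trajectory


def _random_points(n, seed):
    return np.random.default_rng(seed).uniform(-10, 10, (n, 3))


class TestKabsch:
    def test_identity_for_equal_sets(self):
        pts = _random_points(6, 1)
        res = kabsch_superpose(pts, pts)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(res.translation, 0, atol=1e-10)
        assert res.rmsd == pytest.approx(0, abs=1e-10)

    def test_rigid_motion_exactly_recovered(self):
        ref = _random_points(8, 2)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ rot.T + np.array([5.0, 0.0, 0.0])
        res = kabsch_superpose(mobile, ref)
        assert res.rmsd == pytest.approx(0, abs=1e-9)
        assert np.allclose(apply_transform(mobile, res), ref, atol=1e-9)

    def test_rotation_is_proper(self):
        # a near-reflection case must still produce determinant +1
        ref = _random_points(5, 3)
        mobile = ref.copy()
        mobile[:, 0] *= -1
        res = kabsch_superpose(mobile, ref)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_quaternion_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        mobile = rng.uniform(-8, 8, (n, 3))
        reference = rng.uniform(-8, 8, (n, 3))
        ours = kabsch_superpose(mobile, reference).rmsd
        oracle = quaternion_grid_rmsd(mobile, reference, seed=seed)
        assert ours <= oracle + 1e-9  # never worse than any searched rotation
        assert abs(ours - oracle) < 1e-4

    def test_symmetry_of_rmsd(self):
        a = _random_points(7, 4)
        b = _random_points(7, 5)
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            kabsch_superpose(b, a).rmsd, abs=1e-9
        )

    def test_rejects_degenerate_input(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_matches_mdanalysis(self):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        a = _random_points(10, 6)
        b = _random_points(10, 7)
        ours = kabsch_superpose(a, b).rmsd
        theirs = mda_rmsd(a, b, center=True, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-8)


class TestTrajectoryRMSD:
    def test_rigid_motions_give_zero(self, reference_50):
        spec = FluctuationSpec.uniform(50, 0.0, rigid_body_noise=(15, 3), seed=1)
        traj = make_trajectory(reference_50, spec, [], n_frames=10)
        series = trajectory_rmsd(traj)
        assert np.allclose(series.values, 0, atol=1e-6)

    def test_single_frame_equal_to_reference(self, reference_50):
        traj = Trajectory(reference_50, reference_50.coords[None], 400.0)
        series = trajectory_rmsd(traj)
        assert series.values.tolist() == pytest.approx([0.0], abs=1e-12)

    def test_mean_rmsd_matches_gaussian_closed_form(self):
        n_res, n_frames, sigma = 150, 800, 0.5
        ref = make_reference_structure(n_res, seed=21)
        spec = FluctuationSpec.uniform(n_res, sigma, seed=22)
        traj = make_trajectory(ref, spec, [], n_frames=n_frames)
        values = trajectory_rmsd(traj).values
        # rigid fit removes 6 of 3N noise DOF; chi-mean (Jensen) factor applied
        k = 3 * n_res - 6
        expected = sigma * np.sqrt(3 * (1 - 2 / n_res)) * (1 - 1 / (4 * k))
        se = values.std(ddof=1) / np.sqrt(n_frames)
        assert abs(values.mean() - expected) < 3 * se + 2e-3

    def test_empty_selection_errors(self, noisy_trajectory):
        with pytest.raises(ValueError, match="matches no atoms"):
            trajectory_rmsd(noisy_trajectory, atom_selection="XX")

    def test_invariant_under_global_rigid_motion(self, noisy_trajectory):
        rot = Rotation.from_euler("xyz", [10, 40, -30], degrees=True).as_matrix()
        shift = np.array([3.0, -2.0, 7.0])
        moved = Trajectory(
            noisy_trajectory.topology,
            np.einsum("ij,naj->nai", rot, noisy_trajectory.frames) + shift,
            noisy_trajectory.frame_interval,
        )
        a = trajectory_rmsd(noisy_trajectory).values
        b = trajectory_rmsd(moved).values
        # reference stays put, every frame moves rigidly: RMSD must not change
        assert np.allclose(a, b, atol=1e-6)


class TestRMSF:
    def test_identical_frames_give_zero(self, reference_50):
        traj = Trajectory(reference_50, np.repeat(reference_50.coords[None], 5, axis=0), 400.0)
        profile = rmsf(traj)
        assert np.allclose(profile.values, 0, atol=1e-12)

    def test_two_sigma_groups_show_ratio(self):
        ref = make_reference_structure(60, seed=23)
        spec = FluctuationSpec.uniform(60, 0.3, region_plan=[(31, 60, 0.9)], seed=24)
        traj = make_trajectory(ref, spec, [], n_frames=3000)
        profile = rmsf(traj)
        ratio = profile.values[30:].mean() / profile.values[:30].mean()
        assert ratio == pytest.approx(3.0, rel=0.08)

    def test_invariant_to_frame_order(self, noisy_trajectory):
        rng = np.random.default_rng(0)
        perm = rng.permutation(noisy_trajectory.n_frames)
        shuffled = Trajectory(
            noisy_trajectory.topology,
            noisy_trajectory.frames[perm],
            noisy_trajectory.frame_interval,
        )
        a = rmsf(noisy_trajectory).values
        b = rmsf(shuffled).values
        assert np.allclose(a, b, atol=1e-9)

    def test_invariant_under_global_rigid_motion(self, noisy_trajectory):
        rot = Rotation.from_euler("zyx", [25, -10, 5], degrees=True).as_matrix()
        moved = Trajectory(
            noisy_trajectory.topology,
            np.einsum("ij,naj->nai", rot, noisy_trajectory.frames) + 4.0,
            noisy_trajectory.frame_interval,
        )
        assert np.allclose(rmsf(noisy_trajectory).values, rmsf(moved).values, atol=1e-6)

    def test_requires_single_atom_per_residue(self, noisy_trajectory):
        with pytest.raises(ValueError, match="at least 2 frames"):
            rmsf(
                Trajectory(
                    noisy_trajectory.topology, noisy_trajectory.frames[:1], 400.0
                )
            )

    def test_multi_atom_selection_rejected(self, noisy_trajectory):
        # "all" selects both atoms of every residue: per-residue profile impossible
        with pytest.raises(ValueError, match="more than one atom"):
            rmsf(noisy_trajectory, atom_selection="all")


def test_superposed_rmsd_never_exceeds_oracle_transform():
    """Kabsch result is optimal: no oracle-searched rotation beats it."""
    rng = np.random.default_rng(99)
    mobile = rng.uniform(-5, 5, (6, 3))
    reference = rng.uniform(-5, 5, (6, 3))
    ours = kabsch_superpose(mobile, reference).rmsd
    for seed in range(5):
        assert ours <= quaternion_grid_rmsd(mobile, reference, seed=seed) + 1e-9
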