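"""Kabsch superposition, RMSD series, and RMSF profiles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from azidyn.structure_io import Trajectory
from azidyn.superposition import (
    SuperpositionError,
    compute_rmsd_series,
    compute_rmsf,
    kabsch_fit,
    superpose_trajectory,
)
from azidyn.synthetic import make_rigid_motion_trajectory
from conftest import make_chain_structure


def brute_force_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent oracle: minimize RMSD over Euler angles (coarse grid +
    local refinement), never touching the SVD path."""
    Xc = mobile - mobile.mean(axis=0)
    Yc = reference - reference.mean(axis=0)

    def cost(angles):
        R = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((Xc @ R.T - Yc) ** 2, axis=1)))

    grid = np.linspace(-np.pi, np.pi, 13)
    best = min(
        ((a, b, c) for a in grid for b in grid[:7] for c in grid),
        key=cost,
    )
    res = minimize(cost, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return float(res.fun)


class TestKabschFit:
    def test_identity_for_identical_point_sets(self, rng):
        pts = rng.normal(size=(8, 3))
        fit = kabsch_fit(pts, pts)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-10)

    def test_recovers_exact_rigid_motion(self, rng):
        pts = rng.normal(size=(12, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([1.0, 2.0, 3.0])
        fit = kabsch_fit(moved, pts)
        assert fit.rmsd < 1e-10
        np.testing.assert_allclose(fit.rotation @ R, np.eye(3), atol=1e-10)

    def test_proper_rotation_even_for_reflected_input(self, rng):
        pts = rng.normal(size=(6, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        fit = kabsch_fit(mirrored, pts)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_rotation_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(size=(5, 3))
        reference = rng.normal(size=(5, 3))
        fit = kabsch_fit(mobile, reference)
        assert fit.rmsd == pytest.approx(
            brute_force_rmsd(mobile, reference), abs=1e-6
        )

    def test_agrees_with_scipy_align_vectors(self, rng):
        mobile = rng.normal(size=(7, 3))
        reference = rng.normal(size=(7, 3))
        fit = kabsch_fit(mobile, reference)
        rot, rssd = Rotation.align_vectors(
            reference - reference.mean(axis=0), mobile - mobile.mean(axis=0)
        )
        np.testing.assert_allclose(fit.rotation, rot.as_matrix(), atol=1e-8)
        assert fit.rmsd == pytest.approx(rssd / np.sqrt(7), abs=1e-8)

    def test_four_point_single_displacement_matches_oracle(self):
        reference = np.array(
            [[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]]
        )
        mobile = reference.copy()
        mobile[3] += [0.0, 1.0, 0.0]
        fit = kabsch_fit(mobile, reference)
        assert fit.rmsd == pytest.approx(brute_force_rmsd(mobile, reference), abs=1e-6)

    def test_fewer_than_three_points_rejected(self):
        pts = np.zeros((2, 3))
        with pytest.raises(SuperpositionError, match="3 points"):
            kabsch_fit(pts, pts)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(SuperpositionError, match="degenerate|collinear"):
            kabsch_fit(pts, pts)

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(-3.1, 3.1), st.floats(-1.5, 1.5), st.floats(-3.1, 3.1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_exact_rigid_motion_always_recovered(self, a, b, c):
        """Zero residual for any proper rotation + translation."""
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        R = Rotation.from_euler("zyx", [a, b, c]).as_matrix()
        fit = kabsch_fit(pts @ R.T + np.array([1.0, -2.0, 0.5]), pts)
        assert fit.rmsd < 1e-9

    def test_rmsd_invariant_under_common_rigid_transform(self, rng):
        mobile = rng.normal(size=(9, 3))
        reference = rng.normal(size=(9, 3))
        base = kabsch_fit(mobile, reference).rmsd
        R = Rotation.from_euler("zyx", [0.4, 1.2, -0.7]).as_matrix()
        t = np.array([3.0, -2.0, 5.0])
        moved = kabsch_fit(mobile @ R.T + t, reference @ R.T + t).rmsd
        assert moved == pytest.approx(base, abs=1e-10)


class TestSuperposeTrajectory:
    def test_rigid_motion_restored_to_reference(self):
        structure = make_chain_structure(15)
        rots = [Rotation.from_euler("zyx", [a, 0.5, -a]).as_matrix()
                for a in (0.1, 0.9, 2.2)]
        trans = [np.array([1.0, 2.0, 3.0]) * k for k in range(3)]
        traj = make_rigid_motion_trajectory(structure, rots, trans, noise_sigma=0.0)
        sel = np.arange(structure.n_atoms)
        fitted = superpose_trajectory(traj, structure, sel)
        for k in range(3):
            np.testing.assert_allclose(
                fitted.coordinates[k], structure.coordinates, atol=1e-9
            )

    def test_idempotent(self, rng):
        structure = make_chain_structure(12)
        coords = structure.coordinates + rng.normal(0, 0.3, size=(4,) + structure.coordinates.shape)
        traj = Trajectory(coordinates=coords, timestep=5.0)
        sel = np.arange(structure.n_atoms)
        once = superpose_trajectory(traj, structure, sel)
        twice = superpose_trajectory(once, structure, sel)
        np.testing.assert_allclose(
            twice.coordinates, once.coordinates, atol=1e-10
        )


class TestRmsdSeries:
    def test_static_trajectory_gives_zeros(self, chain_structure):
        coords = np.repeat(chain_structure.coordinates[None], 3, axis=0)
        traj = Trajectory(coordinates=coords, timestep=5.0)
        sel = np.arange(chain_structure.n_atoms)
        series = compute_rmsd_series(traj, chain_structure, sel)
        np.testing.assert_allclose(series.rmsd, 0.0, atol=1e-12)

    def test_pure_translation_pythagorean_without_superposition(self, chain_structure):
        coords = chain_structure.coordinates[None] + np.array([3.0, 4.0, 0.0])
        traj = Trajectory(coordinates=coords, timestep=5.0)
        sel = np.arange(chain_structure.n_atoms)
        raw = compute_rmsd_series(traj, chain_structure, sel, superpose=False)
        assert raw.rmsd[0] == pytest.approx(5.0, abs=1e-12)
        fitted = compute_rmsd_series(traj, chain_structure, sel, superpose=True)
        assert fitted.rmsd[0] == pytest.approx(0.0, abs=1e-10)

    def test_times_follow_timestep(self, chain_structure):
        coords = np.repeat(chain_structure.coordinates[None], 4, axis=0)
        traj = Trajectory(coordinates=coords, timestep=2.5)
        series = compute_rmsd_series(
            traj, chain_structure, np.arange(chain_structure.n_atoms)
        )
        np.testing.assert_allclose(series.time, [0.0, 2.5, 5.0, 7.5])


class TestRmsf:
    def test_static_trajectory_gives_zero(self, chain_structure):
        coords = np.repeat(chain_structure.coordinates[None], 5, axis=0)
        traj = Trajectory(coordinates=coords, timestep=5.0)
        profile = compute_rmsf(traj, np.arange(chain_structure.n_atoms))
        np.testing.assert_allclose(profile.rmsf, 0.0, atol=1e-12)

    def test_two_frames_at_plus_minus_d(self):
        base = np.zeros((3, 3))
        base[:, 0] = [0.0, 3.8, 7.6]
        d = 0.7
        coords = np.stack([base + [d, 0, 0], base - [d, 0, 0]])
        traj = Trajectory(coordinates=coords, timestep=5.0)
        profile = compute_rmsf(traj, np.arange(3))
        np.testing.assert_allclose(profile.rmsf, d, atol=1e-12)

    def test_isotropic_gaussian_closed_form(self, rng):
        sigma = 0.3
        base = rng.normal(size=(6, 3)) * 5
        coords = base[None] + rng.normal(0, sigma, size=(20000, 6, 3))
        traj = Trajectory(coordinates=coords, timestep=5.0)
        profile = compute_rmsf(traj, np.arange(6))
        np.testing.assert_allclose(
            profile.rmsf, sigma * np.sqrt(3.0), rtol=0.02
        )

    def test_frame_order_invariance(self, rng):
        coords = rng.normal(size=(50, 4, 3))
        traj = Trajectory(coordinates=coords, timestep=5.0)
        shuffled = Trajectory(
            coordinates=coords[rng.permutation(50)], timestep=5.0
        )
        a = compute_rmsf(traj, np.arange(4)).rmsf
        b = compute_rmsf(shuffled, np.arange(4)).rmsf
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_unsuperposed_flag_warns_in_log(self, chain_structure, caplog):
        coords = np.repeat(chain_structure.coordinates[None], 3, axis=0)
        traj = Trajectory(coordinates=coords, timestep=5.0)
        with caplog.at_level("WARNING"):
            compute_rmsf(traj, np.arange(3), superposed=False)
        assert any("superposed" in r.message for r in caplog.records)
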