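import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from complexdyn import (
    SimSpec,
    Trajectory,
    classify_flexibility,
    ground_truth,
    kabsch,
    rmsd_between,
    rmsd_matrix,
    rmsf,
    simulate,
)
from complexdyn.errors import UnderdeterminedSuperpositionError
from complexdyn.superpose import FluctProfile, FLEX_CLASS_LABELS


def grid_min_rmsd(mobile, target, coarse_deg=12.0):
    """Independent oracle: minimize RMSD over rotations by a Euler-angle grid
    followed by local refinement, never calling the Kabsch solution."""
    P = mobile - mobile.mean(axis=0)
    Q = target - target.mean(axis=0)

    def cost(angles):
        R = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
        return np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))

    g = np.arange(-180.0, 180.0, coarse_deg)
    best, best_ang = np.inf, None
    for a in g:
        for b in np.arange(-90.0, 90.1, coarse_deg):
            for c in g:
                v = cost((a, b, c))
                if v < best:
                    best, best_ang = v, (a, b, c)
    res = minimize(cost, best_ang, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    return min(best, res.fun)


class TestKabsch:
    def test_identical_sets_zero_rmsd_identity_rotation(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        res = kabsch(X, X)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_recovers_applied_rigid_motion(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(7, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Y = X @ R.T + np.array([1.0, 2.0, 3.0])
        res = kabsch(X, Y)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, R, atol=1e-9)
        np.testing.assert_allclose(
            X @ res.rotation.T + res.translation, Y, atol=1e-9
        )

    def test_mirror_image_keeps_proper_rotation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 3))
        Y = X.copy()
        Y[:, 0] *= -1  # reflection
        res = kabsch(X, Y)
        assert res.rmsd > 0.1
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        # the proper-rotation minimum agrees with the independent grid search
        assert res.rmsd == pytest.approx(grid_min_rmsd(X, Y), abs=1e-3)

    def test_matches_rotation_grid_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            k = rng.integers(3, 7)
            X = rng.normal(size=(k, 3))
            Y = rng.normal(size=(k, 3))
            assert kabsch(X, Y).rmsd == pytest.approx(
                grid_min_rmsd(X, Y), abs=1e-3
            )

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(3)
        X, Y = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        R, rssd = Rotation.align_vectors(
            Y - Y.mean(axis=0), X - X.mean(axis=0)
        )
        assert kabsch(X, Y).rmsd == pytest.approx(rssd / np.sqrt(10), abs=1e-9)

    @pytest.mark.parametrize(
        "bad",
        [
            np.zeros((2, 3)),
            np.outer(np.arange(5), [1.0, 0.0, 0.0]),  # collinear
        ],
    )
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(UnderdeterminedSuperpositionError):
            kabsch(bad, bad + 1.0)


class TestRMSDMatrix:
    def test_rigid_motion_scores_zero(self, quiet_traj):
        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        frames = np.stack([quiet_traj.frames[0], quiet_traj.frames[0] @ R.T + 5.0])
        t = Trajectory(topology=quiet_traj.topology, frames=frames)
        assert rmsd_between(t, 0, 1) == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_residual(self):
        """Uniform 1.5x scaling of a centered square: the optimal rotation is
        the identity by symmetry, so RMSD = 0.5 * rms radius = sqrt(2)/2."""
        X = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)
        assert kabsch(X, 1.5 * X).rmsd == pytest.approx(np.sqrt(2) / 2, abs=1e-9)

    def test_symmetry_zero_diagonal_and_triangle_inequality(self, quiet_traj):
        m = rmsd_matrix(quiet_traj.frames[:15])
        v = m.values
        np.testing.assert_allclose(v, v.T)
        assert np.all(np.diag(v) == 0)
        n = v.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-6

    def test_identical_frames_zero_matrix(self, quiet_traj):
        frames = np.repeat(quiet_traj.frames[:1], 3, axis=0)
        m = rmsd_matrix(frames)
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_two_state_block_structure(self, two_state_traj, two_state_spec):
        sub = np.concatenate([two_state_traj.frames[:5], two_state_traj.frames[-5:]])
        v = rmsd_matrix(sub).values
        within = np.concatenate([v[:5, :5][np.triu_indices(5, 1)],
                                 v[5:, 5:][np.triu_indices(5, 1)]])
        between = v[:5, 5:].ravel()
        assert within.max() < between.min()


class TestRMSF:
    def test_static_trajectory_zero_rmsf(self, quiet_traj):
        frames = np.repeat(quiet_traj.frames[:1], 5, axis=0)
        t = Trajectory(topology=quiet_traj.topology, frames=frames)
        prof = rmsf(t)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_isotropic_sigma_recovered_and_doubles(self):
        """sigma per coordinate gives RMSF sigma*sqrt(3); doubling sigma
        doubles the profile (both within sampling error at 2000 frames)."""
        spec = SimSpec(n_res_a=40, n_res_b=30, n_snapshots=2000, sigma=0.5, seed=3)
        prof = rmsf(simulate(spec))
        truth = ground_truth(spec)["rmsf"]
        np.testing.assert_allclose(prof.rmsf, truth, rtol=0.05)
        spec2 = SimSpec(n_res_a=40, n_res_b=30, n_snapshots=2000, sigma=1.0, seed=3)
        prof2 = rmsf(simulate(spec2))
        np.testing.assert_allclose(prof2.rmsf / prof.rmsf, 2.0, rtol=0.1)

    def test_relative_profile_mean_is_one(self, quiet_traj):
        prof = rmsf(quiet_traj)
        assert prof.relative.mean() == pytest.approx(1.0, abs=1e-9)

    def test_initial_reference_mode_runs(self, quiet_traj):
        prof = rmsf(quiet_traj, reference="initial")
        assert np.all(prof.rmsf > 0)


class TestFlexibilityClasses:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.4, "<0.5 (black)"),
            (0.5, "[0.5,1) (blue)"),
            (1.0, "[1,1.5) (light blue)"),
            (1.49, "[1,1.5) (light blue)"),
            (1.7, "[1.5,2) (light green)"),
            (2.2, "[2,2.5) (yellow)"),
            (2.9, "[2.5,3) (orange)"),
            (3.2, ">=3.0 (red)"),
        ],
    )
    def test_bin_edges(self, value, label):
        prof = FluctProfile(
            residues=[("A", 1), ("A", 2)],
            rmsf=np.array([1.0, 1.0]),
            relative=np.array([value, 1.0]),
        )
        assert classify_flexibility(prof).flex_class[0] == label

    def test_monotone_total_mapping(self):
        values = np.linspace(0.0, 4.0, 100)
        prof = FluctProfile(
            residues=[("A", i) for i in range(100)],
            rmsf=np.ones(100),
            relative=values,
        )
        classes = classify_flexibility(prof).flex_class
        ranks = [FLEX_CLASS_LABELS.index(c) for c in classes]
        assert ranks == sorted(ranks)
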