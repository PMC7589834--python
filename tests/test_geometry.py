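"""Kabsch superposition, RMSD/RMSF/B-factor/Rg, equilibration window."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from vardyn.errors import (
    ConfigError, DegenerateInputError, InsufficientFramesError, StructureError,
)
from vardyn.geometry import (
    BFACTOR_PER_RMSF2, ScalarSeries, bfactor_from_rmsf, equilibration_window,
    kabsch_superpose, rg_series, rmsd_series, rmsf_per_residue,
)
from vardyn.structure import Trajectory
from vardyn.synthetic import (
    HarmonicEnsembleSpec, build_ca_chain, sample_harmonic_ensemble,
)

from conftest import make_trajectory


def brute_force_rmsd(mobile, reference, seed=0):
    """Independent oracle: coarse-to-fine search over unit quaternions."""
    rng = np.random.default_rng(seed)
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)

    def batch_rmsd(quats):
        mats = Rotation.from_quat(quats).as_matrix()
        fitted = np.einsum("kab,ib->kia", mats, x)
        return np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=2), axis=1))

    best_q = np.array([0.0, 0.0, 0.0, 1.0])
    best = batch_rmsd(best_q[None])[0]
    for scale in (1.0, 0.3, 0.1, 0.03, 0.01, 0.003, 0.001):
        quats = best_q + scale * rng.standard_normal((3000, 4))
        quats /= np.linalg.norm(quats, axis=1, keepdims=True)
        rmsds = batch_rmsd(quats)
        k = int(np.argmin(rmsds))
        if rmsds[k] < best:
            best, best_q = rmsds[k], quats[k]
    return best


class TestKabsch:
    tetra = np.array([[0.0, 0, 0], [1.5, 0, 0], [0.75, 1.3, 0],
                      [0.75, 0.4, 1.2]])

    def test_identical_coordinates_give_zero(self):
        res = kabsch_superpose(self.tetra, self.tetra)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_translation_invariance(self):
        res = kabsch_superpose(self.tetra + [5.0, 0, 0], self.tetra)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rotation_invariance_and_proper_rotation(self):
        r = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        res = kabsch_superpose(self.tetra @ r.T + [1, 2, 3], self.tetra)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_brute_force_quaternion_oracle(self):
        moved = self.tetra.copy()
        moved[3] += [0.6, -0.5, 0.6]  # ~1 A displacement of one vertex
        res = kabsch_superpose(moved, self.tetra)
        oracle = brute_force_rmsd(moved, self.tetra)
        # random search can only overshoot the optimum
        assert res.rmsd <= oracle + 1e-9
        assert abs(res.rmsd - oracle) < 1e-3

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((6, 3))
        b = rng.standard_normal((6, 3))
        res = kabsch_superpose(a, b)
        _, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        assert res.rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-8)

    def test_shape_and_degeneracy_errors(self):
        with pytest.raises(StructureError):
            kabsch_superpose(self.tetra, self.tetra[:3])
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(self.tetra[:2], self.tetra[:2])
        line = np.outer(np.arange(4.0), [1.0, 0, 0])
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_identical_frames_give_zeros(self):
        traj = make_trajectory(np.repeat(TestKabsch.tetra[None], 4, axis=0))
        series = rmsd_series(traj, selection="CA")
        assert np.allclose(series.values, 0.0)

    def test_rigidly_rotated_frame_gives_zero(self):
        r = Rotation.from_euler("z", 73, degrees=True).as_matrix()
        frames = np.stack([TestKabsch.tetra, TestKabsch.tetra @ r.T + 2.0])
        series = rmsd_series(make_trajectory(frames), selection="CA")
        assert np.allclose(series.values, 0.0, atol=1e-10)

    def test_agrees_with_direct_reimplementation(self):
        ref = build_ca_chain(20)
        traj = sample_harmonic_ensemble(
            HarmonicEnsembleSpec(ref, np.eye(20), 100, seed=5)
        )
        series = rmsd_series(traj, selection="CA")
        # independent oracle: superpose with scipy, then plain RMSD
        coords = traj.coords
        expected = []
        for f in range(coords.shape[0]):
            x = coords[f] - coords[f].mean(0)
            y = coords[0] - coords[0].mean(0)
            rot, _ = Rotation.align_vectors(y, x)
            expected.append(
                np.sqrt(np.mean(np.sum((rot.apply(x) - y) ** 2, axis=1)))
            )
        assert np.allclose(series.values, expected, atol=1e-8)


class TestRmsf:
    def test_static_trajectory_gives_zeros(self):
        traj = make_trajectory(np.repeat(TestKabsch.tetra[None], 3, axis=0))
        assert np.allclose(rmsf_per_residue(traj, "CA"), 0.0)

    def test_single_frame_rejected(self):
        with pytest.raises(InsufficientFramesError):
            rmsf_per_residue(make_trajectory(TestKabsch.tetra), "CA")

    def test_unit_variance_gives_sqrt3(self):
        ref = build_ca_chain(60)
        traj = sample_harmonic_ensemble(
            HarmonicEnsembleSpec(ref, np.eye(60), 4000, seed=6)
        )
        rmsf = rmsf_per_residue(traj, "CA")
        assert np.abs(rmsf.mean() - np.sqrt(3)) / np.sqrt(3) < 0.05

    def test_doubling_displacements_doubles_rmsf(self):
        ref = build_ca_chain(10)
        base = sample_harmonic_ensemble(
            HarmonicEnsembleSpec(ref, np.eye(10), 200, seed=7)
        )
        doubled = Trajectory(
            base.topology,
            ref.coords[0] + 2.0 * (base.coords - ref.coords[0]),
        )
        r1 = rmsf_per_residue(base, "CA")
        r2 = rmsf_per_residue(doubled, "CA")
        # linear up to the (second-order) change in the fitted
        # superposition transforms
        assert np.allclose(r2, 2.0 * r1, rtol=5e-3)


class TestBfactorAndRg:
    def test_bfactor_closed_forms(self):
        import pandas as pd

        rmsf = pd.Series([0.0, 1.0, 0.5], index=[1, 2, 3])
        b = bfactor_from_rmsf(rmsf)
        assert b[1] == 0.0
        assert b[2] == pytest.approx(8 * np.pi**2 / 3, rel=1e-12)
        assert b[3] == pytest.approx(BFACTOR_PER_RMSF2 * 0.25, rel=1e-12)

    def test_two_equal_atoms_rg_is_half_separation(self):
        traj = make_trajectory(
            [[0.0, 0, 0], [2.0, 0, 0]], names=["C1", "C2"],
            elements=["C", "C"], residue_indices=[1, 1],
        )
        assert rg_series(traj).values[0] == pytest.approx(1.0, rel=1e-12)

    def test_unit_mass_cube_rg_is_sqrt3(self):
        corners = np.array(
            [[x, y, z] for x in (0, 2.0) for y in (0, 2.0) for z in (0, 2.0)]
        )
        traj = make_trajectory(corners, names=["C"] * 8, elements=["C"] * 8,
                               residue_indices=[1] * 8)
        rg = rg_series(traj, mass_weighted=False)
        assert rg.values[0] == pytest.approx(np.sqrt(3), rel=1e-12)

    def test_rg_invariant_under_rigid_motion(self):
        r = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        frames = np.stack([TestKabsch.tetra, TestKabsch.tetra @ r.T + 7.0])
        rg = rg_series(make_trajectory(frames), selection="heavy")
        assert rg.values[0] == pytest.approx(rg.values[1], rel=1e-12)


class TestEquilibrationWindow:
    def test_matches_discarding_first_forty_percent(self):
        window = equilibration_window(300, 0.4)
        assert window == range(120, 300)
        assert len(window) == 180

    def test_zero_fraction_keeps_everything(self):
        series = ScalarSeries(np.zeros(25), "rmsd")
        assert equilibration_window(series, 0.0) == range(0, 25)

    def test_single_frame_window_warns(self):
        with pytest.warns(UserWarning, match="single frame"):
            window = equilibration_window(10, 0.99)
        assert window == range(9, 10)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigError):
            equilibration_window(10, 1.0)

    @given(n=st.integers(2, 5000),
           frac=st.floats(0.0, 0.99, allow_nan=False))
    def test_window_always_non_empty_and_in_range(self, n, frac):
        window = equilibration_window(n, frac)
        assert 1 <= len(window) <= n
        assert 0 <= window[0] <= window[-1] < n
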