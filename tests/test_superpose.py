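"""Kabsch superposition against a brute-force rotation search, and the
RMSD/RMSF stability metrics on trajectories with known motion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transportscope.core import Trajectory
from transportscope.errors import DegenerateGeometryError, InsufficientFramesError
from transportscope.superpose import kabsch_superpose, rmsd_series, rmsf
from transportscope.synthetic import rotation_about_axis


def _random_rotation(rng):
    axis = rng.normal(size=3)
    return rotation_about_axis(axis, rng.uniform(0, 2 * np.pi))


def _grid_search_rmsd(mobile, reference, coarse_deg=15.0, levels=6):
    """Brute-force rotation search: coarse Euler grid + local refinement."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)

    def rmsd_of(angles):
        a, b, c = angles
        rot = (
            rotation_about_axis([0, 0, 1], a)
            @ rotation_about_axis([0, 1, 0], b)
            @ rotation_about_axis([0, 0, 1], c)
        )
        moved = m @ rot.T
        return np.sqrt(np.mean(np.sum((moved - r) ** 2, axis=1)))

    step = np.radians(coarse_deg)
    grid = np.arange(0, 2 * np.pi, step)
    beta = np.arange(0, np.pi + 1e-9, step)
    best = None
    for a in grid:
        for b in beta:
            for c in grid:
                v = rmsd_of((a, b, c))
                if best is None or v < best[0]:
                    best = (v, (a, b, c))
    val, angles = best
    for _ in range(levels):
        step /= 2.0
        improved = True
        while improved:
            improved = False
            for d in range(3):
                for sgn in (-1, 1):
                    cand = list(angles)
                    cand[d] += sgn * step
                    v = rmsd_of(cand)
                    if v < val:
                        val, angles = v, tuple(cand)
                        improved = True
    return val


class TestKabsch:
    def test_self_superposition_is_identity(self, rng):
        pts = rng.normal(size=(8, 3))
        tf, val = kabsch_superpose(pts, pts)
        assert val == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tf.translation, 0.0, atol=1e-9)

    def test_rigid_copy_recovers_zero_rmsd(self, rng):
        pts = rng.normal(size=(10, 3)) * 5
        rot = rotation_about_axis([0, 0, 1], np.radians(37.0))
        ref = pts @ rot.T + np.array([1.0, 2.0, 3.0])
        tf, val = kabsch_superpose(pts, ref)
        assert val < 1e-8
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(tf.rotation @ tf.rotation.T, np.eye(3), atol=1e-9)

    def test_matches_rotation_grid_search(self, rng):
        for _ in range(3):
            mobile = rng.normal(size=(5, 3)) * 3
            reference = mobile @ _random_rotation(rng).T + rng.normal(size=(5, 3)) * 0.3
            _, kabsch_val = kabsch_superpose(mobile, reference)
            brute_val = _grid_search_rmsd(mobile, reference)
            assert kabsch_val <= brute_val + 1e-9
            assert brute_val - kabsch_val < 1e-3

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_joint_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(6, 3)) * 4
        b = a + rng.normal(size=(6, 3)) * 0.5
        _, ab = kabsch_superpose(a, b)
        _, ba = kabsch_superpose(b, a)
        assert ab == pytest.approx(ba, abs=1e-8)
        rot = _random_rotation(rng)
        t = rng.normal(size=3) * 10
        _, moved = kabsch_superpose(a @ rot.T + t, b @ rot.T + t)
        assert moved == pytest.approx(ab, abs=1e-8)

    def test_degenerate_inputs(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)
        two = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(two, two)


def _static_trajectory(topology, frame, n=4):
    coords = np.repeat(frame[None], n, axis=0)
    return Trajectory(topology, coords, 0.1 * np.arange(n))


class TestRmsdSeries:
    def test_identical_frames_are_zero(self, toy, toy_traj):
        traj = _static_trajectory(toy_traj.topology, toy_traj.coords[0])
        s = rmsd_series(traj, align_sel="res 1-32 name CA")
        assert np.allclose(s.values, 0.0, atol=1e-10)

    def test_rigid_motion_frames_are_zero(self, toy_traj, rng):
        frame0 = toy_traj.coords[0]
        frames = [frame0]
        for _ in range(3):
            rot = _random_rotation(rng)
            frames.append(frame0 @ rot.T + rng.normal(size=3) * 5)
        traj = Trajectory(toy_traj.topology, np.stack(frames), 0.1 * np.arange(4))
        s = rmsd_series(traj, align_sel="res 1-32 name CA")
        assert np.all(s.values < 1e-8)

    def test_hinge_opening_is_nondecreasing_on_ramp(self, toy, toy_traj):
        cfg = toy.sel_cfg
        scaf = " ".join(
            f"{cfg.tm_ranges[t][0]}-{cfg.tm_ranges[t][1]}" for t in cfg.scaffold_tms
        )
        bund = " ".join(
            f"{cfg.tm_ranges[t][0]}-{cfg.tm_ranges[t][1]}" for t in cfg.bundle_tms
        )
        s = rmsd_series(
            toy_traj, align_sel=f"res {scaf} name CA", measure_sel=f"res {bund} name CA"
        )
        ramp = s.values[20:61]  # the programmed monotone opening
        assert np.all(np.diff(ramp) >= -1e-9)
        assert s.values[60] > s.values[19]


class TestRmsf:
    def test_identical_frames_zero(self, toy_traj):
        traj = _static_trajectory(toy_traj.topology, toy_traj.coords[0], n=3)
        _, _, fl = rmsf(traj, align_sel="res 1-320 name CA")
        assert np.allclose(fl, 0.0, atol=1e-10)

    def test_two_state_oscillation_closed_form(self, toy_traj):
        # one atom alternating +/- d along x in an otherwise static system
        frame = toy_traj.coords[0].copy()
        d = 0.7
        plus, minus = frame.copy(), frame.copy()
        plus[0, 0] += d
        minus[0, 0] -= d
        coords = np.stack([plus, minus, plus, minus])
        traj = Trajectory(toy_traj.topology, coords, 0.1 * np.arange(4))
        static_sel = np.arange(5, 200)
        idx, _, fl = rmsf(traj, align_sel=static_sel, measure_sel=np.array([0]))
        assert fl[0] == pytest.approx(d, abs=1e-8)

    def test_hinge_residues_fluctuate_more_than_scaffold(self, toy, toy_traj):
        cfg = toy.sel_cfg
        scaf_sel = toy.sel_cfg.scaffold_ca(toy_traj.topology)
        lo, hi = cfg.tm_ranges["TM1a"]
        _, _, fl_hinge = rmsf(
            toy_traj, align_sel=scaf_sel, measure_sel=f"res {lo}-{hi} name CA"
        )
        _, _, fl_scaf = rmsf(toy_traj, align_sel=scaf_sel, measure_sel=scaf_sel)
        assert fl_hinge.min() > fl_scaf.max()

    def test_single_frame_is_insufficient(self, toy_traj):
        traj = Trajectory(
            toy_traj.topology, toy_traj.coords[:1], toy_traj.times[:1]
        )
        with pytest.raises(InsufficientFramesError):
            rmsf(traj)
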