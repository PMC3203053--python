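"""SASA against closed forms, and water bookkeeping against brute force."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from transportscope.core import Atom, Topology, Trajectory
from transportscope.errors import ConfigurationError, EmptyInputError
from transportscope.selections import CavityDefinition, SelectionConfig
from transportscope.solvation import (
    cavity_water_count,
    count_waters_near,
    group_sasa_series,
    sasa,
    substrate_center,
    substrate_shell_split,
)
from transportscope.synthetic import rotation_about_axis

PROBE = 1.4


def isolated_area(r):
    return 4.0 * np.pi * (r + PROBE) ** 2


class TestSasa:
    def test_isolated_atom_matches_sphere_area(self):
        res = sasa(np.zeros((1, 3)), np.array([1.7]), probe=PROBE, n_sphere_points=960)
        exact = isolated_area(1.7)  # 120.76 A^2
        assert res.group_total == pytest.approx(exact, rel=0.02)
        assert exact == pytest.approx(120.76, abs=0.01)

    def test_distant_atoms_are_independent(self):
        coords = np.array([[0.0, 0, 0], [20.0, 0, 0]])
        res = sasa(coords, np.array([1.7, 1.7]))
        assert np.allclose(res.per_atom_area, isolated_area(1.7), rtol=1e-12)

    @pytest.mark.parametrize("d", [1.0, 2.0, 3.0, 4.0])
    def test_two_overlapping_spheres_match_cap_formula(self, d):
        r = 1.7
        big = r + PROBE
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        res = sasa(coords, np.array([r, r]), n_sphere_points=3840)
        h = big - d / 2.0  # spherical cap height removed from each sphere
        exact_total = 2 * (4 * np.pi * big**2 - 2 * np.pi * big * h)
        assert res.group_total == pytest.approx(exact_total, rel=0.02)

    def test_point_count_convergence_on_random_clusters(self, rng):
        for _ in range(3):
            coords = rng.uniform(0, 6, size=(20, 3))
            radii = rng.uniform(1.2, 1.9, size=20)
            coarse = sasa(coords, radii, n_sphere_points=960).group_total
            fine = sasa(coords, radii, n_sphere_points=3840).group_total
            assert abs(coarse - fine) / fine < 0.01

    def test_per_atom_area_bounded(self, rng):
        coords = rng.uniform(0, 5, size=(15, 3))
        radii = rng.uniform(1.2, 1.9, size=15)
        res = sasa(coords, radii)
        assert np.all(res.per_atom_area >= 0)
        assert np.all(res.per_atom_area <= 4 * np.pi * (radii + PROBE) ** 2 + 1e-9)

    def test_zero_atoms_raise(self):
        with pytest.raises(EmptyInputError):
            sasa(np.empty((0, 3)), np.empty(0))


class TestGroupSasaSeries:
    def test_exposed_atom_reports_isolated_value(self):
        # a lone atom 30 A away from the rest of the context is unoccluded
        atoms = [
            Atom(1, "CA", "C", "ALA", 1, "A", "protein", 1.7),
            Atom(2, "CA", "C", "ALA", 2, "A", "protein", 1.7),
            Atom(3, "CB", "C", "ALA", 2, "A", "protein", 1.7),
        ]
        top = Topology(atoms)
        frame = np.array([[30.0, 0, 0], [0.0, 0, 0], [1.5, 0, 0]])
        traj = Trajectory(top, np.stack([frame, frame]), np.array([0.0, 0.1]))
        s = group_sasa_series(traj, group_sel="res 1")
        assert np.allclose(s.values, isolated_area(1.7), rtol=1e-9)

    def test_burying_group_under_slab_kills_sasa(self, toy_traj):
        top = toy_traj.topology
        frame = toy_traj.coords[0].copy()
        from transportscope.selections import resolve_selection

        group = resolve_selection(top, "res 921")
        # relocate a slab of atoms (another residue block) into a dense
        # grid surrounding the group
        slab = resolve_selection(top, "res 1-69")
        exposed = group_sasa_series(
            Trajectory(top, frame[None], toy_traj.times[:1]), "res 921"
        ).values[0]
        buried_frame = frame.copy()
        center = frame[group].mean(axis=0)
        grid = np.array(
            [
                [i, j, k]
                for i in range(-3, 4)
                for j in range(-3, 4)
                for k in range(-3, 4)
            ],
            dtype=float,
        ) * 1.4
        n = min(len(grid), len(slab))
        buried_frame[slab[:n]] = center + grid[:n]
        buried = group_sasa_series(
            Trajectory(top, buried_frame[None], toy_traj.times[:1]), "res 921"
        ).values[0]
        assert buried < 0.10 * exposed

    def test_pathway_sasa_tracks_programmed_opening(self, toy, toy_pathway_sasa):
        rho = spearmanr(
            toy_pathway_sasa.values, toy.ground_truth.theta_per_frame
        ).statistic
        assert rho > 0.9

    def test_group_outside_context_is_configuration_error(self, toy_traj):
        with pytest.raises(ConfigurationError):
            group_sasa_series(toy_traj, group_sel="water", context_sel="res 1-32")


def _water_box(n_waters, rng, box=20.0, extra_protein=True):
    atoms = []
    coords = []
    serial = 0
    if extra_protein:
        for i in range(5):
            serial += 1
            atoms.append(Atom(serial, "CA", "C", "ALA", i + 1, "A", "protein", 1.7))
            coords.append(rng.uniform(-3, 3, 3))
    for w in range(n_waters):
        serial += 1
        atoms.append(Atom(serial, "O", "O", "HOH", 100 + w, "A", "water", 1.52))
        coords.append(rng.uniform(-box / 2, box / 2, 3))
    return Topology(atoms), np.array(coords)


class TestWaterCounting:
    def test_no_waters_returns_zero(self):
        top = Topology([Atom(1, "CA", "C", "ALA", 1, "A", "protein", 1.7)])
        assert count_waters_near(top, np.zeros((1, 3)), "res 1", 4.0) == 0

    def test_cutoff_boundary(self):
        eps = 1e-6
        for offset, expected in [(3.0 - eps, 1), (3.0 + eps, 0)]:
            top = Topology(
                [
                    Atom(1, "CA", "C", "ALA", 1, "A", "protein", 1.7),
                    Atom(2, "O", "O", "HOH", 2, "A", "water", 1.52),
                ]
            )
            coords = np.array([[0.0, 0, 0], [offset, 0, 0]])
            assert count_waters_near(top, coords, "res 1", 3.0) == expected

    def test_matches_brute_force_double_loop(self, rng):
        top, coords = _water_box(50, rng)
        target = np.flatnonzero(top.roles == "protein")
        for cutoff in (2.0, 4.0, 8.0):
            brute = sum(
                1
                for w in top.water_oxygen_indices()
                if min(np.linalg.norm(coords[w] - coords[t]) for t in target) <= cutoff
            )
            assert count_waters_near(top, coords, target, cutoff) == brute

    def test_monotone_in_cutoff(self, rng):
        top, coords = _water_box(80, rng)
        target = np.flatnonzero(top.roles == "protein")
        cuts = np.linspace(0.5, 12, 12)
        counts = [count_waters_near(top, coords, target, c) for c in cuts]
        assert np.all(np.diff(counts) >= 0)


class TestCavityCount:
    def test_strict_z_bound_excludes_boundary_water(self, toy, toy_traj):
        cfg = toy.sel_cfg
        cav = cfg.cavity_defs["EC"]
        top = toy_traj.topology
        frame = toy_traj.coords[0].copy()
        wat = top.water_oxygen_indices()
        z0 = substrate_center(top, frame)[2]
        ref = cav.reference_residue
        ref_idx = np.flatnonzero(top.res_ids == ref)
        # place one water just below the lower z bound but near the reference
        target = frame[ref_idx].mean(axis=0)
        frame[wat[0]] = [target[0] * 0.3, target[1] * 0.3, z0 + cav.z_min - 0.1]
        below = cavity_water_count(top, frame, cav, cfg, z0)
        frame[wat[0]][2] = z0 + cav.z_min + 0.1
        above = cavity_water_count(top, frame, cav, cfg, z0)
        assert above == below + 1

    def test_matches_ground_truth_per_frame(self, toy, toy_traj):
        cfg = toy.sel_cfg
        gt = toy.ground_truth
        top = toy_traj.topology
        for f in (0, 25, 50, 75, 99):
            z0 = substrate_center(top, toy_traj.coords[f])[2]
            ec = cavity_water_count(top, toy_traj.coords[f], cfg.cavity_defs["EC"], cfg, z0)
            ic = cavity_water_count(top, toy_traj.coords[f], cfg.cavity_defs["IC"], cfg, z0)
            assert ec == gt.ec_water_count[f]
            assert ic == gt.ic_water_count[f]

    def test_matches_brute_force_on_random_waters(self, rng):
        # small fake system: one reference residue + two "TM" residues
        atoms = []
        coords = []
        serial = 0

        def add(name, res_name, res_id, role, xyz):
            nonlocal serial
            serial += 1
            atoms.append(Atom(serial, name, name[0], res_name, res_id, "A", role, 1.7))
            coords.append(xyz)

        add("CA", "PHE", 1, "protein", [0.0, 0, 0])
        for j in range(4):
            add("CA", "ALA", 10 + j, "protein", [6.0, 0, -4.0 + 3 * j])
        for j in range(4):
            add("CA", "ALA", 20 + j, "protein", [-6.0, 0, -4.0 + 3 * j])
        rng2 = np.random.default_rng(5)
        for w in range(200):
            add("O", "HOH", 100 + w, "water", rng2.uniform(-12, 12, 3))
        top = Topology(atoms)
        coords = np.array(coords)
        cfg = SelectionConfig(tm_ranges={"TMA": (10, 13), "TMB": (20, 23)})
        cav = CavityDefinition(
            side="EC", reference_residue=1, tm_list=["TMA", "TMB"],
            cutoff=7.0, z_min=-5.0, z_max=5.0,
        )
        count = cavity_water_count(top, coords, cav, cfg, z_origin=0.0)
        brute = 0
        tma = np.flatnonzero((top.res_ids >= 10) & (top.res_ids <= 13))
        tmb = np.flatnonzero((top.res_ids >= 20) & (top.res_ids <= 23))
        for w in top.water_oxygen_indices():
            p = coords[w]
            if not (-5.0 < p[2] < 5.0):
                continue
            if np.linalg.norm(p - coords[0]) > 7.0:
                continue
            if min(np.linalg.norm(p - coords[i]) for i in tma) > 7.0:
                continue
            if min(np.linalg.norm(p - coords[i]) for i in tmb) > 7.0:
                continue
            brute += 1
        assert count == brute

    def test_rigid_motion_invariance_about_z(self, toy, toy_traj):
        # joint rotation about the membrane normal + xy translation keeps
        # z-based predicates and all distances intact
        cfg = toy.sel_cfg
        top = toy_traj.topology
        frame = toy_traj.coords[50]
        z0 = substrate_center(top, frame)[2]
        rot = rotation_about_axis([0, 0, 1], 1.1)
        moved = frame @ rot.T + np.array([7.0, -3.0, 2.5])
        z0_moved = substrate_center(top, moved)[2]
        for cav in cfg.cavity_defs.values():
            a = cavity_water_count(top, frame, cav, cfg, z0)
            b = cavity_water_count(top, moved, cav, cfg, z0_moved)
            assert a == b


class TestShellSplit:
    def _system_with_waters(self, water_xyz):
        atoms = [Atom(1, "C1", "C", "5HT", 1, "A", "substrate", 1.7)]
        coords = [[0.0, 0.0, 0.0]]
        for i, xyz in enumerate(water_xyz):
            atoms.append(Atom(2 + i, "O", "O", "HOH", 10 + i, "A", "water", 1.52))
            coords.append(list(xyz))
        return Topology(atoms), np.array(coords)

    def test_symmetric_waters_split_evenly(self):
        top, coords = self._system_with_waters(
            [(0, 0, 2.0), (0, 0, -2.0), (1, 1, 1.0), (1, 1, -1.0)]
        )
        split = substrate_shell_split(top, coords, cutoffs=[3.0])
        assert split[3.0] == (2, 2)

    def test_all_waters_below_center(self):
        top, coords = self._system_with_waters([(0, 0, -1.0), (0.5, 0, -2.0)])
        split = substrate_shell_split(top, coords, cutoffs=[3.0])
        assert split[3.0] == (0, 2)

    def test_matches_brute_force_partition(self, rng):
        water_xyz = rng.uniform(-6, 6, size=(60, 3))
        top, coords = self._system_with_waters(water_xyz)
        for cutoff in (3.0, 4.0):
            split = substrate_shell_split(top, coords, cutoffs=[cutoff])
            sub = coords[0]
            ec = ic = 0
            for w in coords[1:]:
                if np.linalg.norm(w - sub) <= cutoff:
                    if w[2] >= sub[2]:
                        ec += 1
                    else:
                        ic += 1
            assert split[cutoff] == (ec, ic)
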