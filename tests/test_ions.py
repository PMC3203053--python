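"""Ion coordination, hydration, chi1 rotamers, release detection, and the
released-ion pathway trace."""

import numpy as np
import pytest

from transportscope.core import Atom, Topology, Trajectory
from transportscope.errors import MissingAtomError, SelectionError
from transportscope.ions import (
    CoordinationSite,
    ReleaseCriteria,
    chi1_dihedral_series,
    coordination_distances,
    detect_ion_release,
    dihedral_angle,
    ion_hydration_series,
    ion_pathway_trace,
)
from transportscope.synthetic import (
    RES_ASP,
    RES_GLY,
    _place_by_torsion,
    rotation_about_axis,
)


def _simple_system(water_positions=(), ion_pos=(0.0, 0.0, 0.0), n_partners=3):
    atoms = []
    coords = []
    serial = 0
    partner_names = ["CG", "O", "OG"]
    for k in range(n_partners):
        serial += 1
        atoms.append(
            Atom(serial, partner_names[k], partner_names[k][0], "ALA", k + 1,
                 "A", "protein", 1.7)
        )
        coords.append(np.eye(3)[k])
    serial += 1
    ion_serial = serial
    atoms.append(Atom(serial, "NA", "Na", "NA", 50, "A", "ion", 2.27))
    coords.append(np.asarray(ion_pos, dtype=float))
    for i, w in enumerate(water_positions):
        serial += 1
        atoms.append(Atom(serial, "O", "O", "HOH", 100 + i, "A", "water", 1.52))
        coords.append(np.asarray(w, dtype=float))
    return Topology(atoms), np.array(coords), ion_serial


class TestCoordinationDistances:
    def test_unit_axis_partners(self):
        top, coords, ion = _simple_system()
        site = CoordinationSite(ion, partners=[(1, "CG"), (2, "O"), (3, "OG")])
        d = coordination_distances(top, coords, site)
        assert np.allclose(d, 1.0)

    def test_coincident_partner_gives_zero(self):
        top, coords, ion = _simple_system(ion_pos=(1.0, 0.0, 0.0))
        site = CoordinationSite(ion, partners=[(1, "CG")])
        assert coordination_distances(top, coords, site)[0] == 0.0

    def test_matches_per_pair_brute_force(self, rng):
        top, coords, ion = _simple_system(ion_pos=(0.3, -0.2, 0.9))
        coords[:3] = rng.normal(size=(3, 3)) * 4
        site = CoordinationSite(ion, partners=[(1, "CG"), (2, "O"), (3, "OG")])
        d = coordination_distances(top, coords, site)
        brute = [np.linalg.norm(coords[k] - coords[3]) for k in range(3)]
        assert np.allclose(d, brute, atol=1e-12)

    def test_missing_partner_raises(self):
        top, coords, ion = _simple_system()
        site = CoordinationSite(ion, partners=[(1, "ZZ9")])
        with pytest.raises(SelectionError):
            coordination_distances(top, coords, site)


class TestHydration:
    def test_vacuum_system_is_all_zero(self):
        top, coords, ion = _simple_system()
        traj = Trajectory(top, np.stack([coords] * 3), 0.1 * np.arange(3))
        s = ion_hydration_series(traj, CoordinationSite(ion))
        assert np.all(s.values == 0)

    def test_four_shell_waters_counted(self):
        shell = [(2.4, 0, 0), (-2.4, 0, 0), (0, 2.4, 0), (0, -2.4, 0), (0, 0, 9.0)]
        top, coords, ion = _simple_system(water_positions=shell)
        traj = Trajectory(top, coords[None], np.array([0.0]))
        s = ion_hydration_series(traj, CoordinationSite(ion, hydration_cutoff=3.0))
        assert s.values[0] == 4

    def test_toy_hydration_rises_after_release(self, toy, toy_traj):
        site = CoordinationSite(toy.ion_serial, hydration_cutoff=3.0)
        s = ion_hydration_series(toy_traj, site)
        k = toy.ground_truth.release_frame
        assert s.values[k:].min() >= s.values[:k].max()


class TestChi1:
    def _four_atom_residue(self, cg_xyz):
        atoms = [
            Atom(1, "N", "N", "ASP", 9, "A", "protein", 1.55),
            Atom(2, "CA", "C", "ASP", 9, "A", "protein", 1.7),
            Atom(3, "CB", "C", "ASP", 9, "A", "protein", 1.7),
            Atom(4, "CG", "C", "ASP", 9, "A", "protein", 1.7),
        ]
        coords = np.array(
            [[-1.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.5, 0.0, 0.0], list(cg_xyz)]
        )
        return Trajectory(Topology(atoms), coords[None], np.array([0.0]))

    def test_cis_is_zero(self):
        traj = self._four_atom_residue([2.3, 1.2, 0.0])  # same side as N
        s = chi1_dihedral_series(traj, 9)
        assert s.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_anti_is_180(self):
        traj = self._four_atom_residue([2.3, -1.2, 0.0])
        s = chi1_dihedral_series(traj, 9)
        assert abs(s.values[0]) == pytest.approx(180.0, abs=1e-9)

    @pytest.mark.parametrize("target", [60.0, -60.0, 180.0, 37.5])
    def test_constructed_torsion_recovered(self, target):
        n = np.array([-1.0, 1.0, 0.3])
        ca = np.zeros(3)
        cb = np.array([1.5, 0.1, -0.2])
        cg = _place_by_torsion(n, ca, cb, bond=1.52, angle_deg=114.0,
                               torsion_deg=target)
        rec = dihedral_angle(n, ca, cb, cg)
        assert rec == pytest.approx(target, abs=1e-6)

    def test_toy_gauche_to_anti_transition(self, toy, toy_traj):
        s = chi1_dihedral_series(toy_traj, RES_ASP)
        gt = toy.ground_truth
        # file round trip carries 1e-3 A coordinate precision
        assert np.allclose(s.values, gt.chi1_per_frame, atol=0.05)
        k = gt.release_frame
        assert np.allclose(s.values[:k], 60.0, atol=0.05)
        assert np.allclose(s.values[k:], 180.0, atol=0.05)

    def test_glycine_raises_missing_atom(self, toy_traj):
        with pytest.raises(MissingAtomError, match=str(RES_GLY)):
            chi1_dihedral_series(toy_traj, RES_GLY)


class TestDetectRelease:
    def test_permanently_coordinated_ion_returns_none(self):
        top, coords, ion = _simple_system(
            water_positions=[(2.0, 0, 0)] * 0, ion_pos=(0.5, 0.5, 0.0)
        )
        traj = Trajectory(top, np.stack([coords] * 20), 0.1 * np.arange(20))
        site = CoordinationSite(ion)
        assert detect_ion_release(traj, site, ReleaseCriteria(min_dwell=3)) is None

    def test_degenerate_criteria_fire_at_frame_zero(self):
        top, coords, ion = _simple_system(ion_pos=(0.5, 0.5, 0.0))
        traj = Trajectory(top, np.stack([coords] * 5), 0.1 * np.arange(5))
        crit = ReleaseCriteria(contact_cutoff=0.0, min_hydration=0, min_dwell=1)
        assert detect_ion_release(traj, CoordinationSite(ion), crit) == 0

    def test_scripted_release_recovered_exactly(self, toy, toy_traj):
        site = CoordinationSite(toy.ion_serial)
        got = detect_ion_release(toy_traj, site, ReleaseCriteria())
        assert got == toy.ground_truth.release_frame

    def test_monotone_in_criteria_looseness(self, toy, toy_traj):
        site = CoordinationSite(toy.ion_serial)
        strict = detect_ion_release(
            toy_traj, site, ReleaseCriteria(contact_cutoff=4.0, min_hydration=4)
        )
        loose_contact = detect_ion_release(
            toy_traj, site, ReleaseCriteria(contact_cutoff=2.0, min_hydration=4)
        )
        loose_hyd = detect_ion_release(
            toy_traj, site, ReleaseCriteria(contact_cutoff=4.0, min_hydration=0)
        )
        assert loose_contact is not None and loose_contact <= strict
        assert loose_hyd is not None and loose_hyd <= strict


class TestPathwayTrace:
    def test_static_system_gives_identical_positions(self):
        top, coords, ion = _simple_system(ion_pos=(1.0, 2.0, 3.0))
        traj = Trajectory(top, np.stack([coords] * 6), 0.1 * np.arange(6))
        trace = ion_pathway_trace(traj, ion, stride=2, scaffold_sel="protein")
        assert trace.shape == (3, 3)
        assert np.ptp(trace, axis=0).max() < 1e-12

    def test_descending_ion_yields_monotone_trace(self):
        top, coords, ion = _simple_system()
        frames = []
        for k in range(8):
            f = coords.copy()
            f[3] = [0.0, 0.0, -1.0 * k]
            frames.append(f)
        traj = Trajectory(top, np.stack(frames), 0.1 * np.arange(8))
        trace = ion_pathway_trace(traj, ion, scaffold_sel="protein")
        assert np.all(np.diff(trace[:, 2]) < 0)

    def test_global_tumbling_is_removed_by_alignment(self, rng):
        top, coords, ion = _simple_system()
        plain, tumbled = [], []
        for k in range(8):
            f = coords.copy()
            f[3] = [0.0, 0.0, -1.0 * k]
            plain.append(f)
            if k == 0:
                tumbled.append(f)  # shared reference frame
            else:
                rot = rotation_about_axis(rng.normal(size=3), rng.uniform(0, 6.28))
                tumbled.append(f @ rot.T + rng.normal(size=3) * 10)
        t_plain = Trajectory(top, np.stack(plain), 0.1 * np.arange(8))
        t_tumb = Trajectory(top, np.stack(tumbled), 0.1 * np.arange(8))
        a = ion_pathway_trace(t_plain, ion, scaffold_sel="protein")
        b = ion_pathway_trace(t_tumb, ion, scaffold_sel="protein")
        assert np.abs(a - b).max() < 1e-6

    def test_toy_trace_matches_scripted_positions(self, toy, toy_traj):
        scaf = toy.sel_cfg.scaffold_ca(toy_traj.topology)
        trace = ion_pathway_trace(toy_traj, toy.ion_serial, scaffold_sel=scaf)
        assert np.abs(trace - toy.ground_truth.ion_position_per_frame).max() < 0.01
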