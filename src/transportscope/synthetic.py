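"""Synthetic toy-transporter trajectories with exact ground truth.

The generator emulates, with pure geometry and bookkeeping (no force
field), the features of an alternating-access transporter trajectory that
the analysis modules measure:

* ten straight ideal TM helices around a central pore axis (+z is the
  membrane normal); two pore-lining helices (TM1, TM6) sit on a smaller
  circle, the scaffold ring further out,
* the intracellular halves of TM1 and TM6 hinge outward by a scheduled
  angle theta(t), opening the cytoplasmic pathway,
* cavity waters whose per-frame occupancy is a Poisson draw with rate
  proportional to the current opening (intracellular side) or constant
  (extracellular side); all other waters are parked in bulk so that cavity
  membership is unambiguous,
* a bound ion coordinated by two pseudo-residue partner atoms that is
  scripted to leave at a given frame and step down -z into bulk inside a
  fixed first hydration shell,
* a side chain whose chi1 rotates from gauche(+60) to anti(180) at the
  release frame,
* a gate atom pair whose shortest distance steps from 3 A to 8 A at a
  scripted rupture frame,
* a static substrate particle whose geometric centre defines z = 0.

Every scripted quantity is recorded frame-exactly in :class:`GroundTruth`;
cavity ground truth is evaluated by brute force on the emitted coordinates
so it is consistent with the trajectory by construction.  All randomness
flows from the spec's seed; the emitted PDB is byte-identical for equal
specs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import Atom, Topology, Trajectory
from .elements import infer_element, vdw_radius
from .errors import ConfigurationError
from .io import assign_role, write_pdb
from .kinetics import KineticsDataset, michaelis_menten
from .selections import CavityDefinition, GateDefinition, SelectionConfig

# canonical alpha-helix geometry
HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = 100.0  # degrees per residue
CA_RADIUS = 2.3  # A, C-alpha distance from the helix axis

# backbone pseudo-atom placement (ring radius, z offset, phase offset deg)
BACKBONE_ATOMS = (
    ("N", 1.6, -0.6, -28.0),
    ("CA", CA_RADIUS, 0.0, 0.0),
    ("CB", 3.3, 0.1, 15.0),
    ("C", 1.7, 0.8, 22.0),
    ("O", 2.0, 1.0, 40.0),
)

_INNER_TM_RADIUS = 6.0  # pore-lining helices TM1, TM6
_SCAFFOLD_TM_RADIUS = 9.0
# helix phases chosen so the cavity reference residues face the pore axis
_TM_PHASES = {8: 132.0, 5: 304.0}

# special residue ids
RES_GATE_GLU = 920
RES_GATE_ARG = 921
RES_ASP = 930  # chi1 / ion partner residue
RES_GLY = 931  # second ion partner (backbone O)
RES_SUBSTRATE = 940
RES_ION = 950
RES_WATER_START = 1001

SUBSTRATE_NAME = "5HT"

_ION_SITE = np.array([0.0, 4.0, -2.0])
_ION_EXIT_Z = -22.0
_ION_STEP = 1.0  # A per frame along -z after release
_HYDRATION_SHELL = 2.4  # A, octahedral first-shell distance
_N_HYDRATION = 6

_GATE_CLOSED = 3.0
_GATE_OPEN = 8.0


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * (k @ k)


def build_ideal_helix(
    n_res: int,
    origin=(0.0, 0.0, 0.0),
    direction=(0.0, 0.0, 1.0),
    phase_deg: float = 0.0,
) -> np.ndarray:
    """Backbone coordinates of a canonical straight alpha-helix.

    Returns an ``(n_res, 5, 3)`` array ordered as N, CA, CB, C, O with
    1.5 A rise and 100 degree twist per residue, the C-alphas 2.3 A from
    the axis.  The helix is built along +z and rotated to ``direction``;
    output is deterministic in all arguments.
    """
    if n_res < 4:
        raise ConfigurationError("an ideal helix needs at least 4 residues")
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise ConfigurationError("helix direction must be non-zero")
    direction = direction / nrm

    coords = np.empty((n_res, len(BACKBONE_ATOMS), 3))
    for j in range(n_res):
        base_angle = math.radians(phase_deg + j * HELIX_TWIST)
        z = j * HELIX_RISE
        for k, (_, ring_r, dz, dphi) in enumerate(BACKBONE_ATOMS):
            a = base_angle + math.radians(dphi)
            coords[j, k] = (ring_r * math.cos(a), ring_r * math.sin(a), z + dz)

    if not np.allclose(direction, [0, 0, 1]):
        axis = np.cross([0, 0, 1], direction)
        if np.linalg.norm(axis) < 1e-12:  # anti-parallel
            rot = rotation_about_axis([1, 0, 0], math.pi)
        else:
            ang = math.acos(np.clip(np.dot([0, 0, 1], direction), -1, 1))
            rot = rotation_about_axis(axis, ang)
        coords = coords @ rot.T
    return coords + origin


def _place_by_torsion(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place atom d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d) given."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(tor),
         bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class ToyTransporterSpec:
    """Construction parameters of the toy transporter trajectory.

    The defaults define the reference study conditions used throughout the
    test suite: a 100-frame (10 ns at 0.1 ns/frame) trajectory with a
    0 -> 25 degree hinge opening ramped over frames 20..60, gate rupture
    at frame 30, and complete ion release at frame 70.
    """

    n_tms: int = 10
    residues_per_tm: int = 32
    hinge_splits: dict = field(default_factory=lambda: {"TM1": 16, "TM6": 16})
    hinge_start_deg: float = 0.0
    hinge_end_deg: float = 25.0
    hinge_ramp: tuple[int, int] = (20, 60)
    cavity_water_rate: float = 0.6  # expected IC waters per frame per degree
    ic_base_rate: float = 1.0
    ec_water_rate: float = 3.0
    n_waters: int = 110
    ion_release_frame: Optional[int] = 70
    gate_rupture_frame: Optional[int] = 30
    n_frames: int = 100
    frame_dt_ns: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_tms != 10:
            raise ConfigurationError("the toy layout is defined for exactly 10 TMs")
        if self.n_frames < 2:
            raise ConfigurationError("need at least 2 frames")
        if not (0.0 <= self.hinge_start_deg <= 90.0 and 0.0 <= self.hinge_end_deg <= 90.0):
            raise ConfigurationError("hinge angles must lie in [0, 90] degrees")
        for tm, split in self.hinge_splits.items():
            if not 2 <= split <= self.residues_per_tm - 2:
                raise ConfigurationError(
                    f"hinge split of {tm} must lie inside the helix"
                )
        t0, t1 = self.hinge_ramp
        if not 0 <= t0 < t1:
            raise ConfigurationError("hinge ramp frames must satisfy 0 <= start < end")

    def theta_schedule(self) -> np.ndarray:
        """Hinge angle per frame: flat, linear ramp, plateau (degrees)."""
        t0, t1 = self.hinge_ramp
        f = np.arange(self.n_frames, dtype=float)
        frac = np.clip((f - t0) / (t1 - t0), 0.0, 1.0)
        return self.hinge_start_deg + frac * (self.hinge_end_deg - self.hinge_start_deg)


@dataclass
class GroundTruth:
    """Frame-exact record of everything the generator scripted."""

    theta_per_frame: np.ndarray
    ion_position_per_frame: np.ndarray
    gate_distance_per_frame: np.ndarray
    ec_water_ids_per_frame: list
    ic_water_ids_per_frame: list
    chi1_per_frame: np.ndarray
    release_frame: Optional[int]
    rupture_frame: Optional[int]

    @property
    def ec_water_count(self) -> np.ndarray:
        return np.array([len(x) for x in self.ec_water_ids_per_frame])

    @property
    def ic_water_count(self) -> np.ndarray:
        return np.array([len(x) for x in self.ic_water_ids_per_frame])

    def to_json(self, path) -> None:
        payload = {
            "theta_per_frame": self.theta_per_frame.tolist(),
            "ion_position_per_frame": self.ion_position_per_frame.tolist(),
            "gate_distance_per_frame": self.gate_distance_per_frame.tolist(),
            "ec_water_ids_per_frame": self.ec_water_ids_per_frame,
            "ic_water_ids_per_frame": self.ic_water_ids_per_frame,
            "chi1_per_frame": self.chi1_per_frame.tolist(),
            "release_frame": self.release_frame,
            "rupture_frame": self.rupture_frame,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            theta_per_frame=np.array(d["theta_per_frame"]),
            ion_position_per_frame=np.array(d["ion_position_per_frame"]),
            gate_distance_per_frame=np.array(d["gate_distance_per_frame"]),
            ec_water_ids_per_frame=d["ec_water_ids_per_frame"],
            ic_water_ids_per_frame=d["ic_water_ids_per_frame"],
            chi1_per_frame=np.array(d["chi1_per_frame"]),
            release_frame=d["release_frame"],
            rupture_frame=d["rupture_frame"],
        )


@dataclass
class ToyTrajectoryResult:
    """Paths and in-memory objects returned by the generator."""

    pdb_path: Path
    config_path: Path
    ground_truth_path: Path
    ground_truth: GroundTruth
    sel_cfg: SelectionConfig
    topology: Topology
    coords: np.ndarray
    times: np.ndarray
    ion_serial: int

    def trajectory(self) -> Trajectory:
        return Trajectory(self.topology, self.coords, self.times)


def _tm_layout(spec: ToyTransporterSpec):
    """Azimuth, circle radius and phase per TM (1-based index)."""
    layout = {}
    for i in range(1, spec.n_tms + 1):
        phi = math.radians((i - 1) * 360.0 / spec.n_tms)
        radius = _INNER_TM_RADIUS if i in (1, 6) else _SCAFFOLD_TM_RADIUS
        layout[i] = (phi, radius, _TM_PHASES.get(i, 0.0))
    return layout


def _special_residues():
    """Hand-placed pseudo-residues: gate pair, ion partners, substrate.

    Returns ``{res_id: (res_name, [(atom_name, xyz), ...])}``.  The ASP
    side-chain CG atom is a placeholder here; it is re-placed per frame
    from the chi1 schedule.
    """
    glu = [
        ("CA", np.array([13.5, 1.1, -12.5])),
        ("OE1", np.array([14.0, 0.0, -12.0])),
        ("OE2", np.array([14.0, 2.2, -12.0])),
    ]
    arg = [
        ("CA", np.array([18.0, 1.1, -12.5])),
        ("NH1", np.array([17.0, 0.0, -12.0])),
        ("NH2", np.array([17.0, 2.2, -12.0])),
    ]
    asp = [
        ("N", np.array([-1.3, 8.2, -2.5])),
        ("CA", np.array([0.0, 7.5, -3.0])),
        ("CB", np.array([0.3, 6.1, -2.6])),
        ("CG", np.array([0.0, 5.0, -2.0])),  # replaced per frame
    ]
    gly = [
        ("CA", np.array([2.5, 5.5, -0.5])),
        ("O", _ION_SITE + np.array([0.0, 0.0, _HYDRATION_SHELL])),
    ]
    sub = [
        ("C1", np.array([1.2, 0.0, 0.2])),
        ("C2", np.array([-0.6, 1.04, 0.2])),
        ("C3", np.array([-0.6, -1.04, 0.2])),
        ("O1", np.array([0.0, 0.0, 1.0])),
        ("N1", np.array([0.0, 0.0, -1.6])),
    ]
    return {
        RES_GATE_GLU: ("GLU", glu),
        RES_GATE_ARG: ("ARG", arg),
        RES_ASP: ("ASP", asp),
        RES_GLY: ("GLY", gly),
        RES_SUBSTRATE: (SUBSTRATE_NAME, sub),
    }


def _hydration_offsets() -> np.ndarray:
    return _HYDRATION_SHELL * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )


def default_selection_config(spec: ToyTransporterSpec, ion_serial: int) -> SelectionConfig:
    """Selection configuration matching the generated toy system."""
    rpt = spec.residues_per_tm
    tm_ranges = {
        f"TM{i}": ((i - 1) * rpt + 1, i * rpt) for i in range(1, spec.n_tms + 1)
    }
    for tm, split in spec.hinge_splits.items():
        i = int(tm[2:])
        lo = (i - 1) * rpt
        # the intracellular (N-terminal) half carries the hinge; naming
        # follows the field's convention (TM1a and TM6b are intracellular)
        ic_name, ec_name = ("TM1a", "TM1b") if i == 1 else (f"TM{i}b", f"TM{i}a")
        tm_ranges[ic_name] = (lo + 1, lo + split)
        tm_ranges[ec_name] = (lo + split + 1, lo + rpt)

    def resid(tm_index: int, j: int) -> int:
        return (tm_index - 1) * rpt + j

    # pore-facing residues of the static scaffold helices flanking the
    # mobile TM1a/TM6b halves: their solvent exposure grows monotonically
    # as the hinged halves vacate the cytoplasmic pathway
    pathway = [
        resid(5, 5), resid(5, 9), resid(5, 12), resid(5, 16),
        resid(8, 4), resid(8, 8), resid(8, 11), resid(8, 15),
    ]
    cavity_defs = {
        "EC": CavityDefinition(
            side="EC", reference_residue=resid(8, 22),
            tm_list=["TM1", "TM6", "TM8", "TM10"], cutoff=10.0,
            z_min=2.0, z_max=15.0,
        ),
        "IC": CavityDefinition(
            side="IC", reference_residue=resid(5, 12),
            tm_list=["TM1", "TM6", "TM8", "TM5"], cutoff=10.0,
        ),
    }
    gates = [
        GateDefinition(
            name="ic_gate",
            group_a=f"res {RES_GATE_GLU} atoms OE1 OE2",
            group_b=f"res {RES_GATE_ARG} atoms NH1 NH2",
            formed_cutoff=4.0, broken_cutoff=6.0,
        )
    ]
    return SelectionConfig(
        tm_ranges=tm_ranges,
        gates=gates,
        pathway_residues=pathway,
        cavity_defs=cavity_defs,
        scaffold_tms=["TM3", "TM4", "TM5", "TM8", "TM9", "TM10"],
        bundle_tms=["TM1", "TM2", "TM6", "TM7"],
        ion_serials=[ion_serial],
        substrate_res=SUBSTRATE_NAME,
    )


def _brute_force_cavity_ids(coords, topology, cavity, sel_cfg, z_origin):
    """Independent O(waters x atoms) evaluation of the cavity predicates."""
    wat_idx = topology.water_oxygen_indices()
    tm_atom_idx = {
        tm: np.flatnonzero(
            (topology.res_ids >= sel_cfg.tm_ranges[tm][0])
            & (topology.res_ids <= sel_cfg.tm_ranges[tm][1])
        )
        for tm in cavity.tm_list
    }
    ref_idx = np.flatnonzero(topology.res_ids == cavity.reference_residue)
    ids = []
    for w in wat_idx:
        p = coords[w]
        z = p[2] - z_origin
        if cavity.z_min is not None and not z > cavity.z_min:
            continue
        if cavity.z_max is not None and not z < cavity.z_max:
            continue
        if min(np.linalg.norm(coords[i] - p) for i in ref_idx) > cavity.cutoff:
            continue
        ok = True
        for tm in cavity.tm_list:
            d = min(np.linalg.norm(coords[i] - p) for i in tm_atom_idx[tm])
            if d > cavity.cutoff:
                ok = False
                break
        if ok:
            ids.append(int(topology.res_ids[w]))
    return ids


def generate_toy_trajectory(spec: ToyTransporterSpec, outdir) -> ToyTrajectoryResult:
    """Build the toy trajectory, write it to disk, and return ground truth.

    Writes ``traj.pdb`` (multi-model), ``config.yaml`` (run configuration
    with matching selections) and ``ground_truth.json`` into ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rpt = spec.residues_per_tm
    layout = _tm_layout(spec)

    # ---- static topology + base coordinates ------------------------------
    atoms: list[Atom] = []
    base: list[np.ndarray] = []
    serial = 0

    def add_atom(name, res_name, res_id, xyz):
        nonlocal serial
        serial += 1
        el = infer_element(name, res_name)
        atoms.append(
            Atom(serial=serial, name=name, element=el, res_name=res_name,
                 res_id=res_id, chain="A", role=assign_role(res_name, SUBSTRATE_NAME),
                 vdw_radius=vdw_radius(el))
        )
        base.append(np.asarray(xyz, dtype=float))
        return serial

    z0 = -(rpt - 1) * HELIX_RISE / 2.0  # centre each helix on z = 0
    tm_atom_serials: dict[int, list[int]] = {}
    for i in range(1, spec.n_tms + 1):
        phi, radius, phase = layout[i]
        origin = np.array([radius * math.cos(phi), radius * math.sin(phi), z0])
        helix = build_ideal_helix(rpt, origin=origin, phase_deg=phase)
        tm_atom_serials[i] = []
        for j in range(rpt):
            res_id = (i - 1) * rpt + j + 1
            for k, (name, *_rest) in enumerate(BACKBONE_ATOMS):
                s = add_atom(name, "ALA", res_id, helix[j, k])
                tm_atom_serials[i].append(s)

    special = _special_residues()
    special_index: dict[tuple[int, str], int] = {}
    for res_id, (res_name, atom_list) in special.items():
        for name, xyz in atom_list:
            s = add_atom(name, res_name, res_id, xyz)
            special_index[(res_id, name)] = s - 1  # 0-based atom index

    ion_serial = add_atom("NA", "NA", RES_ION, _ION_SITE)
    ion_index = ion_serial - 1

    water_indices = []
    for w in range(spec.n_waters):
        s = add_atom("O", "HOH", RES_WATER_START + w, np.zeros(3))
        water_indices.append(s - 1)
    water_indices = np.array(water_indices)
    n_general = spec.n_waters - _N_HYDRATION
    hydration_idx = water_indices[n_general:]

    topology = Topology(atoms)
    base = np.array(base)
    n_atoms = base.shape[0]

    # per-TM hinge machinery
    hinge = {}
    for tm, split in spec.hinge_splits.items():
        i = int(tm[2:])
        phi, radius, _ = layout[i]
        pivot = np.array(
            [radius * math.cos(phi), radius * math.sin(phi),
             z0 + ((split - 1) + 0.5) * HELIX_RISE]
        )
        axis = np.array([-math.sin(phi), math.cos(phi), 0.0])
        lo = (i - 1) * rpt + 1
        moving = np.flatnonzero(
            (topology.res_ids >= lo) & (topology.res_ids <= lo + split - 1)
        )
        # choose the rotation sign that moves the intracellular end outward
        test = base[moving[0]]
        for sign in (1.0, -1.0):
            rot = rotation_about_axis(axis, sign * math.radians(10.0))
            moved = rot @ (test - pivot) + pivot
            if np.hypot(moved[0], moved[1]) > np.hypot(test[0], test[1]):
                hinge[tm] = (pivot, sign * axis, moving)
                break
    sel_cfg = default_selection_config(spec, ion_serial)

    # ---- per-frame state -------------------------------------------------
    theta = spec.theta_schedule()
    times = spec.frame_dt_ns * np.arange(spec.n_frames)
    coords = np.empty((spec.n_frames, n_atoms, 3))
    gate_d = np.empty(spec.n_frames)
    chi1 = np.empty(spec.n_frames)
    ion_pos = np.empty((spec.n_frames, 3))
    ec_ids, ic_ids = [], []

    glu_idx = [special_index[(RES_GATE_GLU, n)] for n in ("OE1", "OE2")]
    arg_idx = [special_index[(RES_GATE_ARG, n)] for n in ("NH1", "NH2")]
    arg_all = np.flatnonzero(topology.res_ids == RES_GATE_ARG)
    asp_n = special_index[(RES_ASP, "N")]
    asp_ca = special_index[(RES_ASP, "CA")]
    asp_cb = special_index[(RES_ASP, "CB")]
    asp_cg = special_index[(RES_ASP, "CG")]
    hyd_off = _hydration_offsets()

    for f in range(spec.n_frames):
        frame = base.copy()

        # hinge opening
        for tm, (pivot, axis, moving) in hinge.items():
            rot = rotation_about_axis(axis, math.radians(theta[f]))
            frame[moving] = (rot @ (frame[moving] - pivot).T).T + pivot

        # gate rupture: the Arg group jumps away along +x
        ruptured = spec.gate_rupture_frame is not None and f >= spec.gate_rupture_frame
        if ruptured:
            frame[arg_all, 0] += _GATE_OPEN - _GATE_CLOSED
        gate_d[f] = min(
            np.linalg.norm(frame[a] - frame[b]) for a in glu_idx for b in arg_idx
        )

        # chi1 schedule of the Asp-like partner (gauche+ before release, anti after)
        released = spec.ion_release_frame is not None and f >= spec.ion_release_frame
        chi1[f] = 180.0 if released else 60.0
        frame[asp_cg] = _place_by_torsion(
            frame[asp_n], frame[asp_ca], frame[asp_cb],
            bond=1.52, angle_deg=114.0, torsion_deg=chi1[f],
        )

        # ion
        if released:
            ion_pos[f] = (0.0, 0.0, _ION_EXIT_Z - _ION_STEP * (f - spec.ion_release_frame))
        else:
            ion_pos[f] = _ION_SITE
        frame[ion_index] = ion_pos[f]

        # waters: first n_ic into the IC cavity, next n_ec into the EC
        # cavity, the rest parked in bulk; dedicated shell waters follow
        # the ion once it is released
        n_ic = int(min(rng.poisson(spec.ic_base_rate + spec.cavity_water_rate * theta[f]),
                       n_general - 25))
        n_ec = int(min(rng.poisson(spec.ec_water_rate), 20))
        r_ic = np.sqrt(rng.uniform(0, 1, n_ic)) * 1.0
        a_ic = rng.uniform(0, 2 * np.pi, n_ic)
        z_ic = rng.uniform(-7.0, -3.0, n_ic)
        r_ec = np.sqrt(rng.uniform(0, 1, n_ec)) * 1.2
        a_ec = rng.uniform(0, 2 * np.pi, n_ec)
        z_ec = rng.uniform(5.0, 8.5, n_ec)
        n_bulk = n_general - n_ic - n_ec
        r_bk = rng.uniform(28.0, 34.0, n_bulk)
        a_bk = rng.uniform(0, 2 * np.pi, n_bulk)
        z_bk = rng.uniform(18.0, 26.0, n_bulk)

        wpos = np.concatenate([
            np.column_stack([r_ic * np.cos(a_ic), r_ic * np.sin(a_ic), z_ic]),
            np.column_stack([r_ec * np.cos(a_ec), r_ec * np.sin(a_ec), z_ec]),
            np.column_stack([r_bk * np.cos(a_bk), r_bk * np.sin(a_bk), z_bk]),
        ])
        frame[water_indices[:n_general]] = wpos
        if released:
            frame[hydration_idx] = ion_pos[f] + hyd_off
        else:
            r_h = rng.uniform(28.0, 34.0, _N_HYDRATION)
            a_h = rng.uniform(0, 2 * np.pi, _N_HYDRATION)
            z_h = rng.uniform(18.0, 26.0, _N_HYDRATION)
            frame[hydration_idx] = np.column_stack(
                [r_h * np.cos(a_h), r_h * np.sin(a_h), z_h]
            )

        coords[f] = frame

        # ground-truth cavity membership by brute force on the emitted frame
        sub_idx = np.flatnonzero(topology.res_ids == RES_SUBSTRATE)
        z_origin = frame[sub_idx].mean(axis=0)[2]
        ec = _brute_force_cavity_ids(frame, topology, sel_cfg.cavity_defs["EC"],
                                     sel_cfg, z_origin)
        ic = _brute_force_cavity_ids(frame, topology, sel_cfg.cavity_defs["IC"],
                                     sel_cfg, z_origin)
        placed_ic = sorted(int(topology.res_ids[w]) for w in water_indices[:n_ic])
        placed_ec = sorted(
            int(topology.res_ids[w]) for w in water_indices[n_ic:n_ic + n_ec]
        )
        if sorted(ec) != placed_ec or sorted(ic) != placed_ic:
            raise RuntimeError(
                "cavity placement margin violated; generator geometry inconsistent"
            )
        ec_ids.append(ec)
        ic_ids.append(ic)

    gt = GroundTruth(
        theta_per_frame=theta,
        ion_position_per_frame=ion_pos,
        gate_distance_per_frame=gate_d,
        ec_water_ids_per_frame=ec_ids,
        ic_water_ids_per_frame=ic_ids,
        chi1_per_frame=chi1,
        release_frame=spec.ion_release_frame,
        rupture_frame=spec.gate_rupture_frame,
    )

    pdb_path = outdir / "traj.pdb"
    write_pdb(pdb_path, topology, coords)
    gt_path = outdir / "ground_truth.json"
    gt.to_json(gt_path)

    config = {
        "trajectory": [str(pdb_path.name)],
        "topology": str(pdb_path.name),
        "substrate_name": SUBSTRATE_NAME,
        "frame_dt_ns": spec.frame_dt_ns,
        "seed": spec.seed,
        "selections": sel_cfg.to_dict(),
        "analysis": {
            "chi1_residue": RES_ASP,
            "ion": {
                "serial": ion_serial,
                "partners": [[RES_ASP, "CG"], [RES_GLY, "O"]],
                "hydration_cutoff": 3.0,
                "contact_cutoff": 4.0,
            },
            "release": {"contact_cutoff": 4.0, "min_hydration": 4, "min_dwell": 10},
            "gate_min_dwell": 5,
            "shell_cutoffs": [3.0, 4.0],
            "pathway_water_cutoffs": [3.0, 4.0],
            "tilt_pairs": [
                ["scaffold", "bundle"],
                ["scaffold", "TM1a"],
                ["scaffold", "TM6b"],
                ["TM1a", "TM1b"],
                ["TM6b", "TM6a"],
            ],
            "pore": {
                "z_min": -18.0, "z_max": 18.0, "z_step": 0.5,
                "search_radius": 10.0, "grid_step": 0.5,
            },
        },
    }
    config_path = outdir / "config.yaml"
    import yaml

    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    return ToyTrajectoryResult(
        pdb_path=pdb_path, config_path=config_path, ground_truth_path=gt_path,
        ground_truth=gt, sel_cfg=sel_cfg, topology=topology, coords=coords,
        times=times, ion_serial=ion_serial,
    )


def generate_uptake_data(
    K_M: float,
    V_max: float,
    concentrations,
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
    label: str = "synthetic",
    conc_units: str = "mM",
) -> KineticsDataset:
    """Michaelis-Menten rate data with multiplicative Gaussian noise.

    Each replicate is tagged as an independent experiment; rates are
    ``v([S]) * (1 + N(0, noise_cv))`` and the draw order is fixed by the
    seed, so identical arguments yield identical datasets.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    all_conc, all_rates, tags = [], [], []
    for rep in range(n_replicates):
        noise = rng.normal(0.0, noise_cv, conc.size) if noise_cv > 0 else np.zeros(conc.size)
        all_conc.append(conc)
        all_rates.append(michaelis_menten(conc, K_M, V_max) * (1.0 + noise))
        tags.append(np.full(conc.size, rep))
    return KineticsDataset(
        concentrations=np.concatenate(all_conc),
        rates=np.concatenate(all_rates),
        label=label, conc_units=conc_units,
        experiment=np.concatenate(tags),
    )
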