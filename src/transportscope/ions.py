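"""Ion coordination, hydration, side-chain rotamer tracking, and release.

The release detector encodes "fully solvated and without protein
interactions" as: no protein heavy atom within the contact cutoff of the
ion AND at least ``min_hydration`` water oxygens within the hydration
cutoff, sustained for ``min_dwell`` consecutive frames.  Protein contact
is evaluated against *all* protein heavy atoms, not only the named
coordination partners, because a released ion must have left the protein
altogether, not merely its starting site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .core import MetricSeries, Topology, Trajectory
from .errors import ConfigurationError, MissingAtomError, SelectionError
from .superpose import kabsch_superpose
from .selections import SelectionSpec, resolve_selection


@dataclass
class CoordinationSite:
    """An ion and its named coordination partners.

    ``partners`` are ``(res_id, atom_name)`` pairs, ordered as configured;
    ``hydration_cutoff`` counts first-shell waters, ``contact_cutoff``
    defines what still counts as a protein interaction.
    """

    ion_serial: int
    partners: list[tuple[int, str]] = field(default_factory=list)
    hydration_cutoff: float = 3.0
    contact_cutoff: float = 4.0

    def __post_init__(self):
        if self.hydration_cutoff <= 0 or self.contact_cutoff <= 0:
            raise ConfigurationError("coordination cutoffs must be positive")


@dataclass
class ReleaseCriteria:
    """Thresholds defining a completed ion release."""

    contact_cutoff: float = 4.0
    min_hydration: int = 4
    min_dwell: int = 10

    def __post_init__(self):
        if self.min_dwell < 1:
            raise ConfigurationError("min_dwell must be >= 1")


def _partner_indices(topology: Topology, partners) -> list[int]:
    out = []
    for res_id, atom_name in partners:
        hits = np.flatnonzero(
            (topology.res_ids == int(res_id))
            & (np.char.upper(topology.names.astype(str)) == atom_name.upper())
        )
        if hits.size == 0:
            raise SelectionError(
                f"coordination partner {atom_name} of residue {res_id} not found"
            )
        out.append(int(hits[0]))
    return out


def coordination_distances(
    topology: Topology, frame_coords: np.ndarray, site: CoordinationSite
) -> np.ndarray:
    """Ion-to-partner distances (A) in configured partner order."""
    ion = topology.index_of_serial(site.ion_serial)
    idx = _partner_indices(topology, site.partners)
    return np.linalg.norm(frame_coords[idx] - frame_coords[ion], axis=1)


def coordination_distance_series(traj: Trajectory, site: CoordinationSite):
    """One MetricSeries per partner over the trajectory."""
    ion = traj.topology.index_of_serial(site.ion_serial)
    idx = _partner_indices(traj.topology, site.partners)
    series = []
    for k, (res_id, atom_name) in enumerate(site.partners):
        d = np.linalg.norm(traj.coords[:, idx[k]] - traj.coords[:, ion], axis=1)
        series.append(
            MetricSeries(name=f"res{res_id}_{atom_name}", units="A",
                         times=traj.times.copy(), values=d)
        )
    return series


def ion_hydration_series(traj: Trajectory, site: CoordinationSite) -> MetricSeries:
    """Per-frame count of water oxygens within the hydration cutoff of the ion."""
    top = traj.topology
    ion = top.index_of_serial(site.ion_serial)
    wat = top.water_oxygen_indices()
    values = np.zeros(traj.n_frames)
    if wat.size:
        for i in range(traj.n_frames):
            d = np.linalg.norm(traj.coords[i][wat] - traj.coords[i][ion], axis=1)
            values[i] = np.count_nonzero(d <= site.hydration_cutoff)
    return MetricSeries(name="hydration", units="count",
                        times=traj.times.copy(), values=values)


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral of four points, degrees in (-180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    nb1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, nb1) * nb1
    w = b2 - np.dot(b2, nb1) * nb1
    x = np.dot(v, w)
    y = np.dot(np.cross(nb1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def chi1_dihedral_series(traj: Trajectory, res_id: int,
                         chain: Optional[str] = None) -> MetricSeries:
    """Side-chain chi1 torsion (N-CA-CB-CG) of a residue, degrees per frame.

    Raises :class:`MissingAtomError` naming the residue when any of the
    four atoms is absent (e.g. glycine or alanine side chains).
    """
    top = traj.topology
    idx = {}
    for name in ("N", "CA", "CB", "CG"):
        mask = (top.res_ids == res_id) & (np.char.upper(top.names.astype(str)) == name)
        if chain is not None:
            mask &= top.chains == chain
        hits = np.flatnonzero(mask)
        if hits.size == 0:
            raise MissingAtomError(f"residue {res_id} lacks atom {name} (chi1 undefined)")
        idx[name] = int(hits[0])
    values = np.array(
        [
            dihedral_angle(f[idx["N"]], f[idx["CA"]], f[idx["CB"]], f[idx["CG"]])
            for f in traj.coords
        ]
    )
    return MetricSeries(name=f"chi1_res{res_id}", units="deg",
                        times=traj.times.copy(), values=values)


def detect_ion_release(
    traj: Trajectory, site: CoordinationSite, criteria: ReleaseCriteria
) -> Optional[int]:
    """First frame starting a sustained fully-released state, or None.

    A frame qualifies when the ion has no protein heavy atom within
    ``criteria.contact_cutoff`` and at least ``criteria.min_hydration``
    first-shell waters; the state must persist for ``min_dwell`` frames.
    A zero contact cutoff with zero required hydration is vacuously
    satisfied from frame 0.
    """
    top = traj.topology
    ion = top.index_of_serial(site.ion_serial)
    prot = top.protein_heavy_indices()
    wat = top.water_oxygen_indices()

    ok = np.zeros(traj.n_frames, dtype=bool)
    for i in range(traj.n_frames):
        pos = traj.coords[i][ion]
        if criteria.contact_cutoff > 0 and prot.size:
            dmin = cKDTree(traj.coords[i][prot]).query(pos, k=1)[0]
            no_contact = dmin > criteria.contact_cutoff
        else:
            no_contact = True
        if criteria.min_hydration > 0:
            if wat.size:
                d = np.linalg.norm(traj.coords[i][wat] - pos, axis=1)
                hydrated = np.count_nonzero(d <= site.hydration_cutoff) >= criteria.min_hydration
            else:
                hydrated = False
        else:
            hydrated = True
        ok[i] = no_contact and hydrated

    run = 0
    for i, q in enumerate(ok):
        run = run + 1 if q else 0
        if run >= criteria.min_dwell:
            return i - criteria.min_dwell + 1
    return None


def ion_pathway_trace(
    traj: Trajectory,
    ion_serial: int,
    stride: int = 1,
    scaffold_sel: SelectionSpec = "protein name CA",
) -> np.ndarray:
    """Ion positions every ``stride`` frames in the scaffold-aligned frame.

    Each frame is first superposed onto frame 0 via the scaffold C-alpha
    selection so that global tumbling of the protein does not contaminate
    the release pathway.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    top = traj.topology
    ion = top.index_of_serial(ion_serial)
    scaf = resolve_selection(top, scaffold_sel)
    ref = traj.frame(0)
    out = []
    for i in range(0, traj.n_frames, stride):
        tf, _ = kabsch_superpose(traj.coords[i][scaf], ref[scaf])
        out.append(tf.apply(traj.coords[i][ion]))
    return np.asarray(out)
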