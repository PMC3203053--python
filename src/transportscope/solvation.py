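"""Solvent accessibility and water bookkeeping.

SASA uses the Shrake-Rupley point-sampling scheme with a deterministic
golden-spiral placement of test points (default 960 points, probe radius
1.4 A).  Water counting treats the oxygen position as the location of a
water molecule; z coordinates for cavity bounds and the shell split are
measured relative to the substrate centre (geometric centre of the
substrate's heavy atoms), the single z origin the analysis defines.

The SASA occlusion context deliberately excludes waters and ions: an
increase in the SASA of protein residues is read as solvent exposure, and
occluding with explicit solvent would invert that signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import MetricSeries, Topology, Trajectory
from .errors import ConfigurationError, EmptyInputError
from .selections import CavityDefinition, SelectionSpec, resolve_selection

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_SPHERE_POINTS = 960


@dataclass
class SasaResult:
    """Per-atom solvent-accessible areas (A^2) and their total."""

    per_atom_area: np.ndarray
    group_total: float


@lru_cache(maxsize=8)
def _golden_spiral(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points by golden-angle spiral (deterministic)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
    subset: Optional[np.ndarray] = None,
) -> SasaResult:
    """Shrake-Rupley SASA of a set of spheres.

    For each atom, test points on the sphere of radius ``r + probe`` are
    rejected when they fall inside any neighbour's probe-inflated sphere;
    the surviving fraction times the sphere area is the atom's SASA.

    ``subset`` restricts which atoms' areas are computed (all atoms still
    occlude); entries outside the subset report area 0 in
    ``per_atom_area`` and are excluded from ``group_total``.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise EmptyInputError("sasa: zero atoms")
    if coords.shape[0] != radii.shape[0]:
        raise ValueError("coords and radii length mismatch")
    if n_sphere_points < 96:
        raise ValueError("n_sphere_points must be >= 96")
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")

    n = coords.shape[0]
    subset_idx = np.arange(n) if subset is None else np.asarray(subset, dtype=int)
    unit = _golden_spiral(int(n_sphere_points))
    inflated = radii + probe
    tree = cKDTree(coords)

    areas = np.zeros(n)
    for i in subset_idx:
        ri = inflated[i]
        neighbours = tree.query_ball_point(coords[i], ri + inflated.max())
        neighbours = [j for j in neighbours if j != i]
        pts = coords[i] + ri * unit
        if neighbours:
            nb = np.asarray(neighbours, dtype=int)
            # keep only true overlappers
            d = np.linalg.norm(coords[nb] - coords[i], axis=1)
            nb = nb[d < ri + inflated[nb]]
            if nb.size:
                diff = pts[:, None, :] - coords[nb][None, :, :]
                dist2 = np.einsum("pnk,pnk->pn", diff, diff)
                blocked = (dist2 < (inflated[nb] ** 2)[None, :]).any(axis=1)
                frac = 1.0 - blocked.mean()
            else:
                frac = 1.0
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ri * ri
    return SasaResult(per_atom_area=areas, group_total=float(areas[subset_idx].sum()))


def group_sasa_series(
    traj: Trajectory,
    group_sel: SelectionSpec,
    context_sel: Optional[SelectionSpec] = None,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> MetricSeries:
    """Per-frame total SASA of a residue group, occluded by the context.

    The default context is every protein and substrate heavy atom; waters
    and ions never occlude.  The group must be a subset of the context.
    """
    top = traj.topology
    group_idx = resolve_selection(top, group_sel)
    if context_sel is None:
        mask = np.isin(top.roles, ["protein", "substrate"]) & (top.elements != "H")
        context_idx = np.flatnonzero(mask)
    else:
        context_idx = resolve_selection(top, context_sel)
    if not np.all(np.isin(group_idx, context_idx)):
        raise ConfigurationError("SASA group must be contained in the context")

    pos_in_context = np.searchsorted(context_idx, group_idx)
    radii = top.vdw_radii[context_idx]
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        res = sasa(traj.coords[i][context_idx], radii, probe=probe,
                   n_sphere_points=n_sphere_points, subset=pos_in_context)
        values[i] = res.group_total
    return MetricSeries(name="sasa", units="A^2", times=traj.times.copy(), values=values)


# ---------------------------------------------------------------------------
# Water bookkeeping
# ---------------------------------------------------------------------------

def count_waters_near(
    topology: Topology,
    frame_coords: np.ndarray,
    target_sel: SelectionSpec,
    cutoff: float,
) -> int:
    """Number of distinct waters whose oxygen is within ``cutoff`` of the target."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    wat = topology.water_oxygen_indices()
    if wat.size == 0:
        return 0
    target_idx = resolve_selection(topology, target_sel)
    tree = cKDTree(frame_coords[target_idx])
    d, _ = tree.query(frame_coords[wat], k=1)
    return int(np.count_nonzero(d <= cutoff))


def waters_in_cavity(
    topology: Topology,
    frame_coords: np.ndarray,
    cavity: CavityDefinition,
    sel_cfg,
    z_origin: float = 0.0,
) -> np.ndarray:
    """Indices of water oxygens satisfying all cavity predicates.

    Predicates: strict z bounds relative to ``z_origin``; within the cutoff
    of any atom of the reference residue; and within the cutoff of the
    listed TM helices (every one, or any, per ``cavity.tm_logic``).
    """
    wat = topology.water_oxygen_indices()
    if wat.size == 0:
        return wat
    w = frame_coords[wat]
    keep = np.ones(wat.size, dtype=bool)

    z = w[:, 2] - z_origin
    if cavity.z_min is not None:
        keep &= z > cavity.z_min
    if cavity.z_max is not None:
        keep &= z < cavity.z_max

    ref_idx = resolve_selection(topology, f"res {cavity.reference_residue}")
    d_ref, _ = cKDTree(frame_coords[ref_idx]).query(w, k=1)
    keep &= d_ref <= cavity.cutoff

    tm_hits = []
    for tm in cavity.tm_list:
        tm_idx = resolve_selection(topology, sel_cfg.tm_selection(tm))
        d_tm, _ = cKDTree(frame_coords[tm_idx]).query(w, k=1)
        tm_hits.append(d_tm <= cavity.cutoff)
    tm_hits = np.array(tm_hits)
    if tm_hits.size:
        keep &= tm_hits.all(axis=0) if cavity.tm_logic == "all" else tm_hits.any(axis=0)
    return wat[keep]


def cavity_water_count(
    topology: Topology,
    frame_coords: np.ndarray,
    cavity: CavityDefinition,
    sel_cfg,
    z_origin: float = 0.0,
) -> int:
    """Count of waters inside the cavity definition for one frame."""
    return int(waters_in_cavity(topology, frame_coords, cavity, sel_cfg, z_origin).size)


def substrate_center(topology: Topology, frame_coords: np.ndarray,
                     substrate_sel: SelectionSpec = "substrate") -> np.ndarray:
    """Geometric centre of the substrate atoms (the z = 0 reference)."""
    idx = resolve_selection(topology, substrate_sel)
    return frame_coords[idx].mean(axis=0)


def substrate_shell_split(
    topology: Topology,
    frame_coords: np.ndarray,
    substrate_sel: SelectionSpec = "substrate",
    cutoffs: Sequence[float] = (3.0, 4.0),
) -> dict[float, tuple[int, int]]:
    """Waters near the substrate, split into EC/IC halves at its centre.

    Returns ``{cutoff: (ec_count, ic_count)}`` where a water counts when
    its oxygen is within the cutoff of any substrate atom; waters at or
    above the substrate-centre z go to EC (z == 0 is assigned EC by
    convention), below to IC.
    """
    sub_idx = resolve_selection(topology, substrate_sel)
    wat = topology.water_oxygen_indices()
    out: dict[float, tuple[int, int]] = {}
    if wat.size == 0:
        return {float(c): (0, 0) for c in cutoffs}
    com_z = frame_coords[sub_idx].mean(axis=0)[2]
    tree = cKDTree(frame_coords[sub_idx])
    d, _ = tree.query(frame_coords[wat], k=1)
    z = frame_coords[wat][:, 2]
    for c in cutoffs:
        near = d <= c
        ec = int(np.count_nonzero(near & (z >= com_z)))
        ic = int(np.count_nonzero(near & (z < com_z)))
        out[float(c)] = (ec, ic)
    return out
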