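"""Reading topologies and trajectories; writing PDB snapshots.

File parsing is delegated to MDAnalysis (PDB single/multi-model, DCD);
this module validates the records, assigns roles (protein / water / ion /
substrate) deterministically from residue names, and attaches bundled
per-element van der Waals radii.

The default frame spacing is 0.1 ns per frame (a 100 ns trajectory stored
as 1000 snapshots), overridable everywhere a trajectory is loaded.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (
    ROLE_ION,
    ROLE_PROTEIN,
    ROLE_SUBSTRATE,
    ROLE_WATER,
    Atom,
    Topology,
    Trajectory,
)
from .elements import (
    ION_RES_NAMES,
    WATER_RES_NAMES,
    infer_element,
    vdw_radius,
)
from .errors import EmptyInputError, ParseError, TopologyMismatchError

DEFAULT_FRAME_DT_NS = 0.1


def _load_universe(*paths):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(*[str(p) for p in paths])


def _validate_pdb(path: Path) -> int:
    """Cheap record-level validation; returns the number of atom records.

    Raises :class:`ParseError` naming the offending line for records whose
    fixed-width coordinate fields do not parse.
    """
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line) < 54:
                    raise ParseError(f"{path}:{lineno}: truncated atom record")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: unparseable coordinates in atom record"
                    ) from None
                n += 1
    return n


def assign_role(res_name: str, substrate_name: Optional[str]) -> str:
    """Deterministic role assignment from the residue name."""
    res = res_name.strip().upper()
    if substrate_name is not None and res == substrate_name.strip().upper():
        return ROLE_SUBSTRATE
    if res in WATER_RES_NAMES:
        return ROLE_WATER
    if res in ION_RES_NAMES:
        return ROLE_ION
    return ROLE_PROTEIN


def load_topology(path, substrate_name: Optional[str] = None) -> Topology:
    """Read a PDB file into a :class:`Topology`.

    Roles are inferred from residue names (water and ion name tables, the
    configured substrate name, everything else protein); vdW radii come
    from the bundled element table with a documented carbon-like default
    for unknown elements.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".pdb", ".ent", ".pdbqt"):
        n_records = _validate_pdb(path)
        if n_records == 0:
            raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    u = _load_universe(path)
    if len(u.atoms) == 0:
        raise EmptyInputError(f"{path}: zero atoms")

    atoms = []
    for a in u.atoms:
        name = str(a.name)
        res_name = str(a.resname)
        try:
            element = str(a.element).strip()
        except Exception:
            element = ""
        if not element:
            element = infer_element(name, res_name)
        else:
            element = element[0].upper() + element[1:].lower()
        try:
            chain = str(a.chainID)
        except Exception:
            chain = str(getattr(a, "segid", "")) or "A"
        atoms.append(
            Atom(
                serial=int(a.id),
                name=name,
                element=element,
                res_name=res_name,
                res_id=int(a.resid),
                chain=chain.strip() or "A",
                role=assign_role(res_name, substrate_name),
                vdw_radius=vdw_radius(element),
            )
        )
    return Topology(atoms, source_path=path)


def load_trajectory(
    paths: Sequence,
    topology: Topology,
    frame_dt_ns: float = DEFAULT_FRAME_DT_NS,
    t0_ns: float = 0.0,
) -> Trajectory:
    """Read coordinate frames (multi-model PDB and/or DCD) in file order.

    Frame times are synthesised from ``frame_dt_ns`` because snapshot files
    rarely carry trustworthy time stamps.  Every file's atom count must
    match the topology.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    if not paths:
        raise EmptyInputError("no trajectory files given")

    frames: list[np.ndarray] = []
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
        if p.suffix.lower() == ".dcd":
            if topology.source_path is None:
                raise TopologyMismatchError(
                    "reading a DCD needs a topology loaded from a file"
                )
            try:
                u = _load_universe(topology.source_path, p)
            except (OSError, EOFError, ValueError) as exc:
                raise IOError(f"{p}: cannot read DCD frames: {exc}") from exc
        else:
            _validate_pdb(p)
            u = _load_universe(p)
        if len(u.atoms) != topology.n_atoms:
            raise TopologyMismatchError(
                f"{p}: {len(u.atoms)} atoms, topology has {topology.n_atoms}"
            )
        try:
            for ts in u.trajectory:
                frames.append(np.array(ts.positions, dtype=float))
        except (OSError, EOFError) as exc:
            raise IOError(f"{p}: truncated or unreadable frame: {exc}") from exc

    if not frames:
        raise EmptyInputError("trajectory files contain zero frames")
    coords = np.stack(frames)
    times = t0_ns + frame_dt_ns * np.arange(coords.shape[0])
    return Trajectory(topology, coords, times)


# ---------------------------------------------------------------------------
# PDB writing (snapshots, synthetic trajectories, pseudo-atom traces)
# ---------------------------------------------------------------------------

def _pdb_atom_line(serial, name, res_name, chain, res_id, xyz, element) -> str:
    # fixed-width v3.3 layout: name 13-16, altLoc 17, resName 18-21,
    # chain 22, resSeq 23-26, coords 31-54, element 77-78
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"ATOM  {serial:>5d} {name_field:<4s} {res_name:<4s}{chain:1s}{res_id:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


def write_pdb(path, topology: Topology, coords: np.ndarray, multi_model: bool = True) -> None:
    """Write coordinates as a (multi-)model PDB.

    ``coords`` may be a single frame ``(n_atoms, 3)`` or a stack
    ``(n_frames, n_atoms, 3)``.  The writer emits fixed-width records with
    the element column filled, so files round-trip through the reader.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[1] != topology.n_atoms:
        raise TopologyMismatchError(
            f"coords have {coords.shape[1]} atoms, topology has {topology.n_atoms}"
        )
    with open(path, "w") as fh:
        for i_frame, frame in enumerate(coords):
            if multi_model or coords.shape[0] > 1:
                fh.write(f"MODEL     {i_frame + 1:>4d}\n")
            for a, xyz in zip(topology.atoms, frame):
                el = a.element if len(a.element) <= 2 else a.element[:2]
                fh.write(
                    _pdb_atom_line(a.serial % 100000, a.name, a.res_name, a.chain[:1],
                                   a.res_id % 10000, xyz, el.upper())
                )
            if multi_model or coords.shape[0] > 1:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_pseudo_atom_pdb(path, positions: np.ndarray, res_name: str = "SPH") -> None:
    """Write bare pseudo-atoms (pore centres, ion traces) for rendering."""
    positions = np.asarray(positions, dtype=float)
    with open(path, "w") as fh:
        for i, xyz in enumerate(positions, start=1):
            fh.write(_pdb_atom_line(i % 100000, "O", res_name, "X", i % 10000, xyz, "O"))
        fh.write("END\n")
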