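"""Core in-memory containers: topology, trajectory, and metric time series.

Conventions used throughout the package:

* coordinates are Cartesian Angstrom,
* the membrane normal is +z and input files are assumed pre-oriented,
* frame times are nanoseconds,
* residue numbering is taken verbatim from the input file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .errors import EmptyInputError, InsufficientFramesError

ROLE_PROTEIN = "protein"
ROLE_WATER = "water"
ROLE_ION = "ion"
ROLE_SUBSTRATE = "substrate"


@dataclass(frozen=True)
class Atom:
    """One atom record of a topology."""

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str
    role: str
    vdw_radius: float


class Topology:
    """Ordered atom table plus cached numpy views used by the analyses.

    Parameters
    ----------
    atoms:
        Atom records in file order. Serials must be unique and every atom
        must carry a positive van der Waals radius.
    source_path:
        The file the topology was read from, kept so trajectory readers can
        re-open it as the topology source for binary coordinate files.
    """

    def __init__(self, atoms: Iterable[Atom], source_path: Optional[Path] = None):
        self.atoms: list[Atom] = list(atoms)
        if not self.atoms:
            raise EmptyInputError("topology contains zero atoms")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials are not unique")
        for a in self.atoms:
            if not a.vdw_radius > 0:
                raise ValueError(f"atom serial {a.serial} has non-positive vdW radius")
        self.source_path = Path(source_path) if source_path is not None else None
        self.serials = np.array(serials, dtype=int)
        self.names = np.array([a.name for a in self.atoms], dtype=object)
        self.elements = np.array([a.element for a in self.atoms], dtype=object)
        self.res_names = np.array([a.res_name for a in self.atoms], dtype=object)
        self.res_ids = np.array([a.res_id for a in self.atoms], dtype=int)
        self.chains = np.array([a.chain for a in self.atoms], dtype=object)
        self.roles = np.array([a.role for a in self.atoms], dtype=object)
        self.vdw_radii = np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def indices_by_role(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles == role)

    def protein_heavy_indices(self) -> np.ndarray:
        """Protein atoms that are not hydrogen."""
        mask = (self.roles == ROLE_PROTEIN) & (self.elements != "H")
        return np.flatnonzero(mask)

    def water_oxygen_indices(self) -> np.ndarray:
        """One index per water molecule: its oxygen atom.

        The oxygen position is used as the water's location everywhere a
        "water molecule" is counted.
        """
        mask = (self.roles == ROLE_WATER) & (self.elements == "O")
        return np.flatnonzero(mask)

    def index_of_serial(self, serial: int) -> int:
        hits = np.flatnonzero(self.serials == serial)
        if hits.size == 0:
            raise KeyError(f"no atom with serial {serial}")
        return int(hits[0])

    def __len__(self) -> int:
        return self.n_atoms

    def __eq__(self, other) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return self.atoms == other.atoms

    def __repr__(self) -> str:
        return f"<Topology: {self.n_atoms} atoms, {len(set(self.res_ids))} residues>"


class Trajectory:
    """Topology plus an ordered stack of coordinate frames.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Angstrom; ``times``
    are strictly increasing frame times in nanoseconds.
    """

    def __init__(self, topology: Topology, coords: np.ndarray, times: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        times = np.asarray(times, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] == 0:
            raise EmptyInputError("trajectory has zero frames")
        if coords.shape[1] != topology.n_atoms:
            from .errors import TopologyMismatchError

            raise TopologyMismatchError(
                f"trajectory frames have {coords.shape[1]} atoms, "
                f"topology has {topology.n_atoms}"
            )
        if times.shape != (coords.shape[0],):
            raise ValueError("times must have one entry per frame")
        if coords.shape[0] > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.topology = topology
        self.coords = coords
        self.times = times

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def require_frames(self, n: int, what: str) -> None:
        if self.n_frames < n:
            raise InsufficientFramesError(
                f"{what} needs at least {n} frames, trajectory has {self.n_frames}"
            )

    def __len__(self) -> int:
        return self.n_frames

    def __repr__(self) -> str:
        return (
            f"<Trajectory: {self.n_frames} frames x {self.n_atoms} atoms, "
            f"t = {self.times[0]:g}..{self.times[-1]:g} ns>"
        )


@dataclass
class MetricSeries:
    """A named per-frame scalar time series (NaN marks a missing value)."""

    name: str
    units: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        """Write as a two-column CSV (time_ns, value) with full precision."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"time_ns,{self.name}\n")
            for t, v in zip(self.times, self.values):
                fh.write(f"{float(t)!r},{float(v)!r}\n".replace("nan", "NaN"))

    @classmethod
    def from_csv(cls, path, units: str = "") -> "MetricSeries":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().strip().split(",")
            name = header[1] if len(header) > 1 else path.stem
            times, values = [], []
            for line in fh:
                if not line.strip():
                    continue
                t, v = line.strip().split(",")
                times.append(float(t))
                values.append(float(v))
        return cls(name=name, units=units, times=np.array(times), values=np.array(values))
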