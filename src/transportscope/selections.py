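"""Atom selection expressions and the named-selection configuration.

Selection expressions are a small declarative mini-language:

``"res 493 atoms OE1 OE2"``
    all OE1/OE2 atoms of residue 493,
``"res 88-94"``
    every atom of residues 88..94 (inclusive ranges, comma/space lists),
``"res 1-240 name CA"``
    the C-alpha trace of a residue range,
``"chain A res 10-20"``
    chain-scoped selection (each protomer of an oligomer analysed
    independently is addressed through its chain),
``"protein" / "water" / "ion" / "substrate"``
    role keywords.

All clauses are conjunctive.  A selection that resolves to zero atoms is an
error, never an empty result: downstream metrics on empty groups are
meaningless and silently propagating them hides configuration typos.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .core import Topology
from .errors import ConfigurationError, SelectionError

SelectionSpec = Union[str, Sequence[int], np.ndarray]

_ROLE_KEYWORDS = {"protein", "water", "ion", "substrate"}


def _parse_int_list(tokens: list[str], start: int) -> tuple[set[int], int]:
    """Consume integer / "a-b" range tokens from position ``start``."""
    out: set[int] = set()
    i = start
    while i < len(tokens):
        tok = tokens[i]
        if "-" in tok[1:]:  # allow negative single ids, ranges like 88-94
            lo, hi = tok.split("-", 1) if not tok.startswith("-") else (None, None)
            if lo is not None and lo.lstrip("-").isdigit() and hi.isdigit():
                out.update(range(int(lo), int(hi) + 1))
                i += 1
                continue
        if tok.lstrip("-").isdigit():
            out.add(int(tok))
            i += 1
            continue
        break
    if not out:
        raise SelectionError(f"expected residue ids after position {start} in {tokens!r}")
    return out, i


def resolve_selection(topology: Topology, spec: SelectionSpec) -> np.ndarray:
    """Resolve a selection expression to sorted unique atom indices.

    Integer sequences / arrays are passed through (validated and sorted),
    so every API taking a selection accepts either form.  Raises
    :class:`SelectionError` if the result is empty or a referenced residue
    does not exist.
    """
    if isinstance(spec, (list, tuple, np.ndarray)) and not isinstance(spec, str):
        idx = np.asarray(spec, dtype=int)
        if idx.size == 0:
            raise SelectionError("empty index selection")
        if idx.min() < 0 or idx.max() >= topology.n_atoms:
            raise SelectionError("atom index out of range")
        return np.unique(idx)

    tokens = spec.replace(",", " ").split()
    if not tokens:
        raise SelectionError("empty selection expression")

    res_ids: Optional[set[int]] = None
    names: Optional[set[str]] = None
    chain: Optional[str] = None
    role: Optional[str] = None

    i = 0
    while i < len(tokens):
        tok = tokens[i].lower()
        if tok in ("res", "resid", "resi"):
            ids, i = _parse_int_list(tokens, i + 1)
            res_ids = ids if res_ids is None else (res_ids | ids)
        elif tok in ("atoms", "atom", "name", "names"):
            i += 1
            got: set[str] = set()
            while i < len(tokens) and tokens[i].lower() not in (
                "res", "resid", "resi", "atoms", "atom", "name", "names", "chain",
            ) and tokens[i].lower() not in _ROLE_KEYWORDS:
                got.add(tokens[i].upper())
                i += 1
            if not got:
                raise SelectionError(f"'name' clause without atom names in {spec!r}")
            names = got if names is None else (names | got)
        elif tok == "chain":
            i += 1
            if i >= len(tokens):
                raise SelectionError(f"'chain' clause without chain id in {spec!r}")
            chain = tokens[i]
            i += 1
        elif tok in _ROLE_KEYWORDS:
            role = tok
            i += 1
        else:
            raise SelectionError(f"unrecognised token {tokens[i]!r} in selection {spec!r}")

    mask = np.ones(topology.n_atoms, dtype=bool)
    if res_ids is not None:
        present = set(int(r) for r in np.unique(topology.res_ids))
        missing = res_ids - present
        if missing == res_ids:
            raise SelectionError(
                f"selection {spec!r}: none of the referenced residues exist"
            )
        mask &= np.isin(topology.res_ids, sorted(res_ids))
    if names is not None:
        mask &= np.isin(np.char.upper(topology.names.astype(str)), sorted(names))
    if chain is not None:
        mask &= topology.chains == chain
    if role is not None:
        mask &= topology.roles == role

    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    return idx


@dataclass
class GateDefinition:
    """A gate: shortest heavy-atom distance between two charged groups.

    ``formed_cutoff``/``broken_cutoff`` define the hysteresis band used by
    event detection (an interaction counts as broken only above the broken
    cutoff, and as reformed only below the formed cutoff).
    """

    name: str
    group_a: SelectionSpec
    group_b: SelectionSpec
    formed_cutoff: float = 4.0
    broken_cutoff: float = 6.0

    def __post_init__(self):
        if not (self.broken_cutoff > self.formed_cutoff > 0):
            raise ConfigurationError(
                f"gate {self.name!r}: need broken_cutoff > formed_cutoff > 0"
            )


@dataclass
class CavityDefinition:
    """A solvent cavity: waters near a reference residue and a set of TMs.

    A water belongs to the cavity when its oxygen lies (i) strictly inside
    the z bounds (if given, measured relative to the configured z origin),
    (ii) within ``cutoff`` of any atom of the reference residue, and (iii)
    within ``cutoff`` of the listed TM helices -- of every one of them when
    ``tm_logic == "all"`` (default), of at least one when ``"any"``.
    """

    side: str  # "EC" or "IC"
    reference_residue: int
    tm_list: list[str]
    cutoff: float = 10.0
    z_min: Optional[float] = None
    z_max: Optional[float] = None
    tm_logic: str = "all"

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ConfigurationError("cavity cutoff must be positive")
        if self.z_min is not None and self.z_max is not None and not self.z_min < self.z_max:
            raise ConfigurationError("cavity z_min must be below z_max")
        if self.tm_logic not in ("all", "any"):
            raise ConfigurationError("tm_logic must be 'all' or 'any'")


@dataclass
class SelectionConfig:
    """Named residue/atom groups shared by all analyses.

    ``tm_ranges`` maps TM names (including sub-ranges such as ``TM1a``) to
    inclusive residue-id ranges; the scaffold and bundle lists name the
    static and mobile domains of the rocking-bundle description.
    """

    tm_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    gates: list[GateDefinition] = field(default_factory=list)
    pathway_residues: list[int] = field(default_factory=list)
    cavity_defs: dict[str, CavityDefinition] = field(default_factory=dict)
    scaffold_tms: list[str] = field(default_factory=list)
    bundle_tms: list[str] = field(default_factory=list)
    ion_serials: list[int] = field(default_factory=list)
    substrate_res: Optional[str] = None
    chain: Optional[str] = None

    def __post_init__(self):
        overlap = set(self.scaffold_tms) & set(self.bundle_tms)
        if overlap:
            raise ConfigurationError(
                f"scaffold and bundle TM sets must be disjoint, share {sorted(overlap)}"
            )

    # -- selection helpers -------------------------------------------------
    def _chain_prefix(self) -> str:
        return f"chain {self.chain} " if self.chain else ""

    def tm_selection(self, tm_name: str, ca_only: bool = False) -> str:
        if tm_name not in self.tm_ranges:
            raise SelectionError(f"unknown TM name {tm_name!r}")
        lo, hi = self.tm_ranges[tm_name]
        sel = f"{self._chain_prefix()}res {lo}-{hi}"
        return sel + (" name CA" if ca_only else "")

    def tm_group_selection(self, tm_names: Sequence[str], topology: Topology,
                           ca_only: bool = False) -> np.ndarray:
        parts = [resolve_selection(topology, self.tm_selection(t, ca_only=ca_only))
                 for t in tm_names]
        return np.unique(np.concatenate(parts))

    def scaffold_ca(self, topology: Topology) -> np.ndarray:
        return self.tm_group_selection(self.scaffold_tms, topology, ca_only=True)

    def bundle_ca(self, topology: Topology) -> np.ndarray:
        return self.tm_group_selection(self.bundle_tms, topology, ca_only=True)

    def pathway_selection(self) -> str:
        ids = " ".join(str(r) for r in self.pathway_residues)
        return f"{self._chain_prefix()}res {ids}"

    def validate(self, topology: Topology) -> None:
        """Check that every referenced residue exists in the topology."""
        present = set(int(r) for r in np.unique(topology.res_ids))
        wanted: set[int] = set(self.pathway_residues)
        for lo, hi in self.tm_ranges.values():
            wanted.update((lo, hi))
        for cav in self.cavity_defs.values():
            wanted.add(cav.reference_residue)
        missing = wanted - present
        if missing:
            raise SelectionError(
                f"configured residues absent from topology: {sorted(missing)}"
            )

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "tm_ranges": {k: list(v) for k, v in self.tm_ranges.items()},
            "gates": [
                {
                    "name": g.name, "group_a": g.group_a, "group_b": g.group_b,
                    "formed_cutoff": g.formed_cutoff, "broken_cutoff": g.broken_cutoff,
                }
                for g in self.gates
            ],
            "pathway_residues": list(self.pathway_residues),
            "cavity_defs": {
                k: {
                    "side": c.side, "reference_residue": c.reference_residue,
                    "tm_list": list(c.tm_list), "cutoff": c.cutoff,
                    "z_min": c.z_min, "z_max": c.z_max, "tm_logic": c.tm_logic,
                }
                for k, c in self.cavity_defs.items()
            },
            "scaffold_tms": list(self.scaffold_tms),
            "bundle_tms": list(self.bundle_tms),
            "ion_serials": list(self.ion_serials),
            "substrate_res": self.substrate_res,
            "chain": self.chain,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionConfig":
        return cls(
            tm_ranges={k: (int(v[0]), int(v[1])) for k, v in d.get("tm_ranges", {}).items()},
            gates=[GateDefinition(**g) for g in d.get("gates", [])],
            pathway_residues=[int(r) for r in d.get("pathway_residues", [])],
            cavity_defs={k: CavityDefinition(**c) for k, c in d.get("cavity_defs", {}).items()},
            scaffold_tms=list(d.get("scaffold_tms", [])),
            bundle_tms=list(d.get("bundle_tms", [])),
            ion_serials=[int(s) for s in d.get("ion_serials", [])],
            substrate_res=d.get("substrate_res"),
            chain=d.get("chain"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"selections": self.to_dict()}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SelectionConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "selections" in data:
            data = data["selections"]
        return cls.from_dict(data)
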