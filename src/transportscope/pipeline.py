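"""End-to-end analysis battery over one or more trajectories.

``run_all`` executes the full measurement suite -- stability, gates,
solvation, ions, helices, pore -- from a single YAML configuration,
writing one CSV/JSON per metric plus a manifest recording parameters,
input checksums and per-stage status.  Stages are isolated: a failure in
one is recorded and later independent stages still run.

The "most inward-facing" snapshot is exported as the frame maximising the
cytoplasmic-pathway SASA (ties broken toward the earliest frame), the
same criterion used to pick a representative inward-open structure from a
transition trajectory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import Trajectory
from .errors import TransportScopeError
from .gates import detect_state_change, gate_distance_series
from .helices import tilt_angle_series
from .io import load_topology, load_trajectory, write_pdb, write_pseudo_atom_pdb
from .ions import (
    CoordinationSite,
    ReleaseCriteria,
    chi1_dihedral_series,
    coordination_distance_series,
    detect_ion_release,
    ion_hydration_series,
    ion_pathway_trace,
)
from .pore import PoreProfile, pore_radius_profile
from .selections import SelectionConfig
from .solvation import (
    cavity_water_count,
    count_waters_near,
    group_sasa_series,
    substrate_center,
    substrate_shell_split,
)
from .superpose import rmsd_series, rmsf


@dataclass
class RunConfig:
    """Everything one analysis run needs, loadable from YAML."""

    trajectory: list[Path]
    topology: Path
    selections: SelectionConfig
    substrate_name: Optional[str] = None
    frame_dt_ns: float = 0.1
    seed: int = 0
    analysis: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent
        traj = [base / p for p in raw["trajectory"]]
        topo = base / raw.get("topology", raw["trajectory"][0])
        for p in traj + [topo]:
            if not p.exists():
                raise FileNotFoundError(p)
        return cls(
            trajectory=traj,
            topology=topo,
            selections=SelectionConfig.from_dict(raw["selections"]),
            substrate_name=raw.get("substrate_name"),
            frame_dt_ns=float(raw.get("frame_dt_ns", 0.1)),
            seed=int(raw.get("seed", 0)),
            analysis=raw.get("analysis", {}),
        )

    def load(self) -> Trajectory:
        top = load_topology(self.topology, substrate_name=self.substrate_name)
        return load_trajectory(self.trajectory, top, frame_dt_ns=self.frame_dt_ns)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _tm_ca_selection(cfg: SelectionConfig) -> str:
    base_tms = [t for t in cfg.tm_ranges if t[-1].isdigit()]
    ranges = " ".join(f"{cfg.tm_ranges[t][0]}-{cfg.tm_ranges[t][1]}" for t in base_tms)
    return f"res {ranges} name CA"


def _expand_group(name, cfg: SelectionConfig) -> list[str]:
    if name == "scaffold":
        return list(cfg.scaffold_tms)
    if name == "bundle":
        return list(cfg.bundle_tms)
    return [name]


def run_all(config: RunConfig, outdir) -> dict:
    """Run the full battery; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.selections
    ana = config.analysis
    manifest: dict = {
        "package_version": __version__,
        "inputs": {str(p): _sha256(p) for p in config.trajectory},
        "parameters": {
            "frame_dt_ns": config.frame_dt_ns,
            "substrate_name": config.substrate_name,
            "seed": config.seed,
            "analysis": ana,
        },
        "stages": {},
    }

    traj = config.load()
    cfg.validate(traj.topology)
    times = traj.times
    state: dict = {}

    def stage(name):
        def deco(fn):
            try:
                outputs = fn()
                manifest["stages"][name] = {"status": "ok", "outputs": outputs}
            except (TransportScopeError, ValueError, KeyError) as exc:
                manifest["stages"][name] = {
                    "status": "error",
                    "error": f"{type(exc).__name__}: {exc}",
                    "outputs": [],
                }
            return fn

        return deco

    @stage("stability")
    def _stability():
        tm_ca = _tm_ca_selection(cfg)
        rs = rmsd_series(traj, align_sel=tm_ca)
        rs.to_csv(outdir / "rmsd.csv")
        idx, res_ids, fl = rmsf(traj, align_sel=tm_ca)
        pd.DataFrame({"res_id": res_ids, "rmsf_A": fl}).to_csv(
            outdir / "rmsf.csv", index=False
        )
        return ["rmsd.csv", "rmsf.csv"]

    @stage("gates")
    def _gates():
        dwell = int(ana.get("gate_min_dwell", 5))
        cols = {"time_ns": times}
        events = {}
        for gate in cfg.gates:
            s = gate_distance_series(traj, gate)
            cols[gate.name] = s.values
            events[gate.name] = [
                {"event": e, "frame": int(f), "time_ns": float(times[f])}
                for e, f in detect_state_change(s, gate, min_dwell=dwell)
            ]
        pd.DataFrame(cols).to_csv(outdir / "gates.csv", index=False)
        with open(outdir / "events.json", "w") as fh:
            json.dump(events, fh, indent=2)
        return ["gates.csv", "events.json"]

    @stage("solvation")
    def _solvation():
        outputs = []
        sasa_s = group_sasa_series(traj, cfg.pathway_selection())
        sasa_s.to_csv(outdir / "sasa_pathway.csv")
        state["pathway_sasa"] = sasa_s.values
        outputs.append("sasa_pathway.csv")

        wcuts = ana.get("pathway_water_cutoffs", [3.0, 4.0])
        cols = {"time_ns": times}
        for c in wcuts:
            cols[f"waters_within_{c:g}A"] = [
                count_waters_near(traj.topology, traj.coords[i],
                                  cfg.pathway_selection(), c)
                for i in range(traj.n_frames)
            ]
        pd.DataFrame(cols).to_csv(outdir / "pathway_waters.csv", index=False)
        outputs.append("pathway_waters.csv")

        if cfg.cavity_defs:
            have_sub = cfg.substrate_res is not None
            cols = {"time_ns": times}
            for name, cav in cfg.cavity_defs.items():
                counts = []
                for i in range(traj.n_frames):
                    z0 = (
                        substrate_center(traj.topology, traj.coords[i])[2]
                        if have_sub else 0.0
                    )
                    counts.append(
                        cavity_water_count(traj.topology, traj.coords[i], cav, cfg, z0)
                    )
                cols[name] = counts
            pd.DataFrame(cols).to_csv(outdir / "cavity_waters.csv", index=False)
            outputs.append("cavity_waters.csv")

        if cfg.substrate_res is not None:
            scuts = ana.get("shell_cutoffs", [3.0, 4.0])
            cols = {"time_ns": times}
            for c in scuts:
                cols[f"ec_{c:g}A"] = []
                cols[f"ic_{c:g}A"] = []
            for i in range(traj.n_frames):
                split = substrate_shell_split(traj.topology, traj.coords[i],
                                              cutoffs=scuts)
                for c in scuts:
                    ec, ic = split[float(c)]
                    cols[f"ec_{c:g}A"].append(ec)
                    cols[f"ic_{c:g}A"].append(ic)
            pd.DataFrame(cols).to_csv(outdir / "shell_split.csv", index=False)
            outputs.append("shell_split.csv")
        return outputs

    @stage("ions")
    def _ions():
        ion_cfg = ana.get("ion")
        if not ion_cfg:
            return []
        site = CoordinationSite(
            ion_serial=int(ion_cfg["serial"]),
            partners=[(int(r), str(n)) for r, n in ion_cfg.get("partners", [])],
            hydration_cutoff=float(ion_cfg.get("hydration_cutoff", 3.0)),
            contact_cutoff=float(ion_cfg.get("contact_cutoff", 4.0)),
        )
        outputs = []
        if site.partners:
            series = coordination_distance_series(traj, site)
            cols = {"time_ns": times}
            for s in series:
                cols[s.name] = s.values
            pd.DataFrame(cols).to_csv(outdir / "coordination.csv", index=False)
            outputs.append("coordination.csv")
        hyd = ion_hydration_series(traj, site)
        hyd.to_csv(outdir / "hydration.csv")
        outputs.append("hydration.csv")

        chi_res = ana.get("chi1_residue")
        if chi_res is not None:
            chi = chi1_dihedral_series(traj, int(chi_res))
            chi.to_csv(outdir / "chi1.csv")
            outputs.append("chi1.csv")

        rel_cfg = ana.get("release", {})
        criteria = ReleaseCriteria(
            contact_cutoff=float(rel_cfg.get("contact_cutoff", 4.0)),
            min_hydration=int(rel_cfg.get("min_hydration", 4)),
            min_dwell=int(rel_cfg.get("min_dwell", 10)),
        )
        rel = detect_ion_release(traj, site, criteria)
        with open(outdir / "release.json", "w") as fh:
            json.dump(
                {
                    "release_frame": rel,
                    "release_time_ns": None if rel is None else float(times[rel]),
                },
                fh, indent=2,
            )
        outputs.append("release.json")

        scaf_ca = cfg.scaffold_ca(traj.topology)
        trace = ion_pathway_trace(traj, site.ion_serial, stride=1, scaffold_sel=scaf_ca)
        pd.DataFrame(trace, columns=["x", "y", "z"]).assign(time_ns=times).to_csv(
            outdir / "pathway_trace.csv", index=False
        )
        write_pseudo_atom_pdb(outdir / "pathway_trace.pdb", trace[:: max(1, len(trace) // 50)])
        outputs += ["pathway_trace.csv", "pathway_trace.pdb"]
        return outputs

    @stage("helices")
    def _helices():
        pair_names = ana.get(
            "tilt_pairs", [["scaffold", "bundle"], ["scaffold", "TM1a"], ["TM1a", "TM1b"]]
        )
        pairs = [
            (_expand_group(a, cfg), _expand_group(b, cfg)) for a, b in pair_names
        ]
        series = tilt_angle_series(traj, pairs, cfg)
        cols = {"time_ns": times}
        for (a, b), s in zip(pair_names, series.values()):
            cols[f"{a}/{b}"] = s.values
        pd.DataFrame(cols).to_csv(outdir / "angles.csv", index=False)
        return ["angles.csv"]

    @stage("pore")
    def _pore():
        p = ana.get("pore", {})
        z_range = (float(p.get("z_min", -15.0)), float(p.get("z_max", 15.0)))
        kwargs = dict(
            z_range=z_range,
            z_step=float(p.get("z_step", 0.5)),
            search_radius=float(p.get("search_radius", 10.0)),
            grid_step=float(p.get("grid_step", 0.5)),
        )
        frames = {"first": 0, "last": traj.n_frames - 1}
        if "pathway_sasa" in state:
            frames["inward"] = int(np.argmax(state["pathway_sasa"]))
        outputs = []
        regions = {}
        for label, f in frames.items():
            prof: PoreProfile = pore_radius_profile(
                traj.topology, traj.coords[f], **kwargs
            )
            pd.DataFrame(
                {
                    "z": prof.z_values, "radius_A": prof.radii,
                    "cx": prof.center_points[:, 0], "cy": prof.center_points[:, 1],
                    "cz": prof.center_points[:, 2],
                    "unbounded": prof.unbounded.astype(int),
                }
            ).to_csv(outdir / f"pore_{label}.csv", index=False)
            regions[label] = {
                "frame": f,
                "EC_mean_radius_A": prof.region_mean(z_lo=1e-9),
                "IC_mean_radius_A": prof.region_mean(z_hi=-1e-9),
            }
            outputs.append(f"pore_{label}.csv")
        with open(outdir / "pore_regions.json", "w") as fh:
            json.dump(regions, fh, indent=2)
        outputs.append("pore_regions.json")
        return outputs

    @stage("snapshot")
    def _snapshot():
        if "pathway_sasa" not in state:
            raise TransportScopeError("pathway SASA unavailable; snapshot not exported")
        f = int(np.argmax(state["pathway_sasa"]))
        write_pdb(outdir / "inward_snapshot.pdb", traj.topology, traj.coords[f],
                  multi_model=False)
        manifest["inward_snapshot_frame"] = f
        manifest["inward_snapshot_time_ns"] = float(times[f])
        return ["inward_snapshot.pdb"]

    manifest["ok"] = all(
        s["status"] == "ok" for s in manifest["stages"].values()
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
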