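"""Shared fixtures: a session-scoped toy transporter trajectory.

The toy system is generated once per session with a fixed seed and loaded
back through the package's own file readers, so every test downstream of
the fixtures also exercises the PDB round trip.
"""

from __future__ import annotations

import numpy as np
import pytest

from transportscope.io import load_topology, load_trajectory
from transportscope.pipeline import RunConfig, run_all
from transportscope.solvation import group_sasa_series
from transportscope.synthetic import ToyTransporterSpec, generate_toy_trajectory

TOY_SEED = 7


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """Reference toy trajectory: 100 frames, hinge 0->25 deg over frames
    20..60, gate rupture at 30, ion release at 70."""
    outdir = tmp_path_factory.mktemp("toy")
    return generate_toy_trajectory(ToyTransporterSpec(seed=TOY_SEED), outdir)


@pytest.fixture(scope="session")
def toy_traj(toy):
    """The toy trajectory loaded back from its multi-model PDB."""
    top = load_topology(toy.pdb_path, substrate_name="5HT")
    return load_trajectory([toy.pdb_path], top)


@pytest.fixture(scope="session")
def toy_pathway_sasa(toy, toy_traj):
    """Pathway SASA series of the toy trajectory (computed once)."""
    return group_sasa_series(toy_traj, toy.sel_cfg.pathway_selection())


@pytest.fixture(scope="session")
def pipeline_result(toy, tmp_path_factory):
    """Full run_all output on the toy system."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = RunConfig.from_yaml(toy.config_path)
    manifest = run_all(config, outdir)
    return outdir, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
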