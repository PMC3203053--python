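# transportscope

Trajectory analysis for alternating-access membrane transporters.

Secondary transporters of the LeuT fold (the neurotransmitter sodium
symporters among them) move their substrate by switching between an
outward-facing and an inward-facing conformation. Detecting that switch in
molecular-dynamics trajectories is not one measurement but a battery of
them: gate salt-bridge distances, solvent-accessible surface area (SASA) of
pathway residues, water occupancy of the extra- and intracellular cavities,
ion-coordination and ion-release tracking, helix tilt and hinge angles of
the rocking four-helix bundle, and pore radius profiles along the membrane
normal. `transportscope` implements that battery as a tested, reusable
library and CLI for people who run MD on transporters and need the standard
gating metrics without re-deriving them per project — plus the one-site
uptake-kinetics regression used to connect simulation to cell-based
transport assays.

## What it computes

* **Stability** — Kabsch superposition, Cα RMSD time series, per-residue
  RMSF after alignment on a chosen selection.
* **Gates** — shortest heavy-atom distance between charged groups (e.g.
  Arg guanidinium vs. Glu carboxylate), with hysteresis break/reform event
  detection (broken when d > broken cutoff for a dwell, reformed when
  d < formed cutoff).
* **Solvation** — Shrake–Rupley SASA (deterministic golden-spiral points,
  probe 1.4 Å), water counts near residue sets, cavity occupancy
  (z bounds + distance to a reference residue and to a list of TM
  helices), and water shells around the substrate split at the substrate
  centre (z = 0).
* **Ions** — coordination distances, first-shell hydration, χ1 (N–CA–CB–CG)
  rotamer tracking, release detection (no protein heavy atom within the
  contact cutoff *and* ≥ n waters in the first shell, sustained), and the
  scaffold-aligned release pathway trace.
* **Helix geometry** — principal-axis helix/group axes with N→C
  orientation, scaffold/bundle tilt angles, TM1a/TM1b and TM6a/TM6b hinge
  angles, and classification of a frame's bundle orientation against
  labelled reference conformations.
* **Pore** — largest-free-sphere radius per z slice (the classic pore
  profile objective) via a deterministic grid + shrinking-grid search.
* **Kinetics** — nonlinear least squares fit of the one-site hyperbola
  v = V·[S]/(K_M + [S]) with asymptotic standard errors, t-based 95%
  confidence limits, saturation flagging, and wild-type/mutant K_M fold
  change with an unpaired t-test over per-experiment fits.
* **Synthetic data** — a toy 10-TM transporter generator that scripts a
  hinge opening, occupancy-coupled cavity waters, a gate rupture and an
  ion release with frame-exact ground truth, so the whole pipeline is
  testable end to end without external data.

## Worked example

```python
import numpy as np
from transportscope import (
    load_topology, load_trajectory, tilt_angle_series,
    detect_ion_release, fit_michaelis_menten,
)
from transportscope.ions import CoordinationSite, ReleaseCriteria
from transportscope.synthetic import (
    ToyTransporterSpec, generate_toy_trajectory, generate_uptake_data,
)

# a ground-truthed toy transporter: 100 frames (0.1 ns/frame), hinge
# opening 0 -> 25 degrees over frames 20..60, Na+ release scripted at 70
res = generate_toy_trajectory(ToyTransporterSpec(seed=1), "out/toy")
top = load_topology(res.pdb_path, substrate_name="5HT")
traj = load_trajectory([res.pdb_path], top)

hinge = tilt_angle_series(traj, [(["TM1a"], ["TM1b"])], res.sel_cfg)["TM1a/TM1b"]
print(f"hinge angle: {hinge.values[0]:.2f} deg -> {hinge.values[-1]:.2f} deg")

frame = detect_ion_release(traj, CoordinationSite(res.ion_serial), ReleaseCriteria())
print(f"Na+ release detected at frame {frame} ({traj.times[frame]:.1f} ns)")

data = generate_uptake_data(K_M=5.9, V_max=100.0,
                            concentrations=np.array([1, 2, 5, 10, 25, 50, 100, 150.0]),
                            noise_cv=0.05, n_replicates=3, seed=1)
fit = fit_michaelis_menten(data)
print(f"K_M = {fit.K_M:.2f} mM  [{fit.ci95_KM[0]:.2f}; {fit.ci95_KM[1]:.2f}], "
      f"V_max = {fit.V_max:.1f}")
```

Output:

```
hinge angle: 0.68 deg -> 24.77 deg
Na+ release detected at frame 70 (7.0 ns)
K_M = 6.23 mM  [5.69; 6.76], V_max = 101.7
```

The hinge series recovers the programmed 0→25° opening (the residual at
frame 0 is the principal-axis discretisation of a 16-residue helix half),
the release detector returns exactly the scripted frame, and the kinetics
fit recovers the generating K_M within its confidence interval.

The same battery runs from the shell:

```
transportscope synth --out toy --seed 1
transportscope run-all --config toy/config.yaml --out results
```

which writes `rmsd.csv`, `gates.csv` + `events.json`, `sasa_pathway.csv`,
`cavity_waters.csv`, `coordination.csv`, `release.json`, `angles.csv`,
`pore_*.csv`, the most inward-facing snapshot (`inward_snapshot.pdb`, the
frame maximising pathway SASA) and a `manifest.json` with input checksums
and per-stage status.

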