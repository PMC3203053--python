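# Methods

This note documents the models and conventions behind each analysis, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that affect reproducibility.

## Conventions

Coordinates are Cartesian Ångström; the membrane normal is +z and inputs
are assumed pre-oriented (the synthetic generator writes oriented files).
Frame times are nanoseconds, synthesised from a configurable frame spacing
(default 0.1 ns — a 100 ns trajectory stored as 1000 snapshots) because
snapshot files rarely carry trustworthy clocks. Residue numbering is taken
verbatim from the input file; protomers of an oligomer are analysed
independently through chain-scoped selections. Atom roles (protein, water,
ion, substrate) are assigned deterministically from residue names, with
the substrate residue name supplied by the caller. Van der Waals radii are
the bundled Bondi per-element set (C 1.70, N 1.55, O 1.52, S 1.80,
Na 2.27, Cl 1.75 Å, …) with a carbon-like 1.70 Å default for unknown
elements; monoatomic ions use element rather than charge-state radii.
These radii enter only SASA and pore profiling, where a fixed documented
set matters more than any particular choice.

## Superposition and stability

Rigid superposition is the Kabsch SVD solution with the standard
reflection guard (if the optimal orthogonal matrix has determinant −1 the
smallest singular axis is flipped, so a proper rotation is always
returned). Collinear or <3-point inputs are rejected as degenerate. The
RMSD reference is the first frame by default (configurable); nothing in a
snapshot stream distinguishes a better reference. RMSF aligns every frame
on the alignment selection, computes the mean structure in a single pass,
and measures fluctuations about it; iterative mean refinement changes the
result by far less than the tolerances used anywhere in the package. No
mass weighting: all stability metrics are Cα-based.

## Gates

A gate is the shortest heavy-atom distance between two named atom groups.
The charged-group atoms (carboxylate O pair, guanidinium N pair, hydroxyl
O) are named explicitly in the configuration rather than perceived from
chemistry — this keeps the package free of a chemistry-perception
dependency and makes selections auditable. Event detection uses hysteresis
with defaults formed < 4.0 Å, broken > 6.0 Å and a 5-frame dwell: a single
cutoff on a thermally fluctuating distance produces event storms, and the
literature's "lost"/"reforms" language is qualitative, so the cutoffs are
explicit, documented and configurable. Events alternate by construction
(a state machine emits a break only from the formed state and vice versa);
the initial state is read off the first frame.

## Solvation

SASA is Shrake–Rupley with 960 test points per atom placed by a
golden-angle spiral — deterministic, so repeated runs are bit-identical —
and probe radius 1.4 Å. Occlusion is evaluated against all protein and
substrate heavy atoms; waters and ions never occlude, because the analyses
read SASA increases as solvent exposure and occluding with explicit
solvent would invert that signal. At 960 points the isolated-sphere error
is below 2% and refinement to 3840 points moves cluster totals by <1%.

A water molecule is located at its oxygen. Cavity occupancy requires,
conjunctively: strict z bounds (when configured) measured relative to the
substrate's geometric centre — the single z origin the analysis defines,
also used for the substrate shell split (z ≥ 0 counts as extracellular,
with the boundary assigned EC by convention); distance ≤ cutoff (default
10 Å) to any atom of a reference residue; and distance ≤ cutoff to each
listed TM helix. Whether "near TM1, TM6, TM8 and TM10" should read as
*every* helix or *any* helix is genuinely ambiguous in common usage; the
default is conjunctive (`tm_logic: all`) with a documented switch, since
the conjunctive reading is the most literal and the stricter one.
Substrate centre is geometric (unweighted): masses are not carried by the
topology, and for the ~20-atom substrates concerned the COM–centroid
difference is far below the 3–4 Å shell cutoffs.

## Ions

Coordination traces are raw distances to named partner atoms; no
coordination cutoff is imposed because summaries like "continuous
coordination partner" are threshold-dependent, and thresholding is left
to the caller as post-processing. χ1 is the signed N–CA–CB–CG torsion in
(−180°, 180°]. Ion release is declared at the first frame opening a run
(default 10 frames) in which the ion has no protein heavy atom within the
contact cutoff (default 4.0 Å) *and* at least `min_hydration` (default 4,
a typical first-shell count for Na⁺) water oxygens within the hydration
cutoff (3.0 Å). Contact is tested against all protein heavy atoms, not
just the starting-site partners: a released ion has left the protein, not
merely its binding site. Loosening either criterion can only move the
detected frame earlier (tested as a monotonicity property). The release
pathway trace superposes each frame's scaffold Cαs onto frame 0 before
recording the ion position, so global tumbling does not contaminate the
pathway.

## Helix geometry

A helix axis is the principal axis (largest-variance eigenvector) of its
Cα coordinates, sign-fixed toward the N→C direction and flipped by a
per-helix polarity so every axis reports the intracellular→extracellular
orientation regardless of how the helix threads the membrane. Group axes
(scaffold, four-helix bundle) pool the member Cαs before the fit rather
than averaging per-helix axes — pooling stays well-defined when members
differ in length and is insensitive to how the membership list is split.
Tilt angles are unsigned angles between oriented axes in [0°, 180°],
computed frame-internally (no global alignment), hence exactly invariant
under rigid motion. Hinge angles (TM1a vs TM1b, TM6a vs TM6b) are the same
operation on configured sub-ranges; the split residues are configuration
entries because unwound-segment boundaries are a modelling choice, not
something the geometry can infer. One accuracy caveat is inherent to the
principal-axis definition: for short helix segments the discrete Cα spiral
biases the axis away from the true helix axis by up to a few tenths of a
degree (≈0.35° at 16 residues, worse below ~12); hinge-angle recovery is
therefore quoted to 2°. Conformational-state classification superposes the
frame's scaffold onto each labelled reference, measures the angle between
bundle axes in the common frame, and reports the nearest label.

## Pore profile

For each z slice the profile radius is that of the largest sphere centred
in the slice plane, within a search radius of the nominal axis, that
overlaps no blocking atom's vdW sphere — the classic pore-profile
objective. The centre search is a deterministic coarse grid (spacing
0.5 Å) followed by shrinking-grid descent to grid/16 resolution, replacing
the Monte Carlo annealing of classic implementations so that profiles are
exactly reproducible run to run; the objective itself is unchanged. Only
protein and substrate heavy atoms block (configurable); waters and ions
are excluded, matching how pore programs are conventionally run on MD
snapshots. Slices with no atoms within search_radius + 20 Å report the
search radius and an `unbounded` flag instead of failing. The profile axis
is the membrane normal; curved pore-path following is out of scope, and on
a sparse ring-model test structure the search radius must be set small
enough to stay inside the channel (open exterior space would otherwise win
the maximisation). Defaults: z step 0.5 Å, search radius 10 Å, grid step
0.5 Å.

## Uptake kinetics

The one-site hyperbola v = V_max·[S]/(K_M + [S]) is fitted by
Levenberg–Marquardt least squares with analytic Jacobian, initialised at
V_max⁰ = max rate and K_M⁰ = the concentration nearest half-max, followed
by Gauss–Newton polishing to the normal-equation fixed point so the
estimate depends on the objective alone, not the solver path. Rates are
normalised by their maximum internally, which makes the fit exactly
equivariant under rescaling the rate units. Standard errors are asymptotic
(from the Jacobian at the optimum) and 95% confidence limits use the t
distribution with n−2 degrees of freedom. A fit whose K_M exceeds the
largest tested concentration is flagged as unsaturated: the estimate is an
extrapolation, and comparisons against it are reported as lower bounds
("≥ fold change") rather than point values — the bound construction itself
is left to the caller, since truncation versus constrained refitting is a
reporting convention, not a statistical one. Replicates are pooled by
default; per-experiment fitting (for the unpaired t-test on K_M between
wild type and mutant) activates when observations carry experiment tags.
At least 4 distinct concentrations are required. Under the simulation
conditions used in the tests (8 concentrations spanning 0.1–10×K_M, 5%
multiplicative Gaussian noise) the median relative K_M error is ≈7% and
CI coverage ≈94%.

## Synthetic toy transporter

The generator builds geometry and bookkeeping only — no force field, no
solvent dynamics. Ten straight ideal α-helices (1.5 Å rise, 100° twist,
2.3 Å Cα radius; backbone N/CA/CB/C/O pseudo-atoms on concentric rings)
stand on circles around the pore axis: the two pore-lining helices TM1 and
TM6 at 6 Å, the rest at 9 Å. 32 residues per TM, split 16/16 for the
hinged helices; 16-residue halves keep the principal-axis bias of each
half below 0.4° so hinge recovery is meaningful at the 2° tolerance. The
intracellular halves of TM1 and TM6 rotate outward about a tangential axis
through the split point by θ(t): flat at 0°, linear ramp to 25° over
frames 20–60, plateau — emulating the hinge-type opening of the
cytoplasmic pathway while the extracellular side stays packed.

Scripted events and their defaults (the reference study conditions of the
test suite): 100 frames at 0.1 ns; gate pseudo-residues (Glu OE1/OE2 vs
Arg NH1/NH2) whose shortest distance steps 3 Å → 8 Å at frame 30; an ion
coordinated by two partner pseudo-atoms (an Asp-like CG at χ1 = +60°,
a backbone O at 2.4 Å) until frame 70, when the Asp χ1 rotates to 180°
(gauche→anti) and the ion jumps below the protein and steps 1 Å/frame
along −z inside a fixed octahedral shell of six waters at 2.4 Å; a static
5-atom substrate centred at the origin defining z = 0. Water occupancy is
a per-frame Poisson draw — intracellular cavity rate 1 + 0.6·θ(t) waters
per degree of opening, extracellular rate constant at 3 — realised by
moving waters from a bulk reservoir (the atom count is constant across
frames, as in real MD); cavity placements carry geometric margin against
every cavity predicate, and the recorded ground truth is an independent
brute-force evaluation of those predicates on the emitted coordinates, so
trajectory and ground truth cannot disagree. The pathway-residue set is
chosen on the static scaffold helices facing the pore: their exposure
grows monotonically as the hinged halves vacate the pathway (rank
correlation with θ(t) ≈ 0.98), whereas residues on the moving halves
themselves pass transiently closer to the scaffold ring and are
non-monotone. All randomness flows from a single seed; equal specs produce
byte-identical PDB output.

What passing on the toy does **not** show about real data: there is no
thermal noise on protein coordinates, no solvent physics, no periodic
boundary images, no helix irregularity or unwinding, and the scripted
events are step functions rather than diffusive transitions. The toy
validates the *bookkeeping and geometry* of every metric against exact
ground truth — thresholds for real trajectories (gate cutoffs, release
criteria, dwell times) still need tuning to the noise level of the system
under study.

## Pipeline

`run_all` executes stability → gates → solvation → ions → helices → pore
from one YAML configuration. Stages are isolated: an error is recorded in
the manifest and later stages still run; the manifest also carries input
SHA-256 checksums and all parameters, and contains no timestamps so reruns
are byte-identical. The exported "most inward-facing" snapshot is the
frame maximising cytoplasmic-pathway SASA, ties broken toward the earliest
frame. Problem sizes throughout the test battery (≈1700 atoms, ≤110
waters, 100 frames) were chosen so the entire suite, including two full
pipeline runs, completes in a few minutes on a single core.

## Known limitations

* No PSF/topology-builder support, no trajectory writing, no PBC imaging.
* Pore profiling follows a straight axis only.
* Helix axes assume reasonably straight segments; strongly kinked helices
  should be split into sub-ranges via the configuration.
* Hydrogen-bond donor–H–acceptor geometry is not evaluated; gate traces
  are heavy-atom distances.
* The kinetics module fits one-site hyperbolas only (no Hill, substrate
  inhibition, or global shared-parameter fits).
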