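# Methods

## Scope and model of the analysis

`c1screen` treats a membrane–ligand trajectory as a sequence of independent
configurations of an orthorhombic, axis-aligned periodic box containing a
flat bilayer patch, water, counterions, and `n` copies of one ligand. Every
observable it reports is a configurational time average (or a histogram of
per-frame samples); nothing depends on dynamical correlations. That choice
fixes two conventions used throughout:

* **Membrane normal = box z axis.** For a flat patch of ~10²
  lipids the instantaneous fitted normal deviates negligibly from z, and a
  single global normal makes the tilt angle unambiguous. Curved or
  undulating membranes are out of scope.
* **Leaflet folding.** Each leaflet has an outward normal (+z upper, −z
  lower, pointing from the bilayer center toward water). Tilt angles are
  measured against the outward normal of the leaflet that hosts the
  ligand's hydroxy group, and depths are folded to nonnegative distances
  from the bilayer center. Both leaflets therefore contribute to a single
  population map, and a ligand mirrored through the midplane produces an
  identical (θ, depth) sample — a property the tests check exactly.

The bilayer center is the mass-weighted *circular* mean of the lipid z
coordinates (angle representation on the periodic box). This makes the
center well defined even when the bilayer straddles the z boundary and
makes every (θ, depth) sample exactly invariant under rigid translation of
the whole box modulo periodicity.

## Ligand geometry

The ligand's central axis vector is COM(axis head) − COM(axis tail). By
default the tail is the heteroaromatic core ring and the head is the
hydroxy oxygen, configurable per candidate in `LigandSpec`: with this
choice the axis points the hydroxymethyl group toward water exactly when θ
is small, which is what "correct" orientation means for a DAG mimetic.
Copies are unwrapped across periodic boundaries (breadth-first minimum-image
unwrap over the bond graph) before any COM is taken. A zero-length axis or
a disconnected bond graph raises immediately rather than producing a
garbage angle.

## Heat map and classifier

(θ, depth) samples accumulate into a raw-count 2D histogram, default 5° ×
0.05 nm bins (the working resolution of the published population maps is
unstated; both widths are config keys echoed into every report). Counts are
kept unnormalised so Σcounts = n_samples holds exactly; normalisation to a
probability map happens only at plotting time. The classifier uses the
*modal cell* — the screening argument is about where the main population
sits, not the mean — with deterministic tie-breaking toward smaller θ, then
smaller depth. Default thresholds

| parameter | default | meaning |
|---|---|---|
| θ_ok | 60° | correct requires mode θ ≤ θ_ok |
| d_ok | 1.4 nm | correct requires mode depth ≥ d_ok |
| θ_bad | 120° | incorrect requires mode θ ≥ θ_bad |
| d_bad | 1.2 nm | incorrect requires mode depth ≤ d_bad |

are calibrated to sit between the reference populations (positive control
near θ ≲ 50°, depth ~1.6 nm; negative control near θ ≳ 130°, depth ~1 nm)
with a deliberate ambiguous gap; they are not taken from any printed rule.
Opposing-orientation weight (samples with θ on the far side of 90° from the
mode) is reported as `secondary_population_fraction`, not penalised: small
flipped populations are expected even for good candidates.

## Density profiles and interface

Partial densities are *mass* densities (kg·m⁻³): whole-molecule and
few-atom-group profiles then share one scale. Each frame is recentered on
the lipid COM before binning (removes slow bilayer drift that would smear
μs-scale profiles); atoms are assigned to signed-z bins by minimum image,
and the bin grid spans the smallest whole number of bins covering the box
height so group mass is conserved exactly (the tests require < 0.1 %,
the implementation achieves ~1e-12 relative). Signed profiles are kept; a
|z|-folded view is a plotting option. The lipid–water interface is the
outermost genuine sign change of (water − lipid) density per half-space,
linearly interpolated (zero plateaus between opposite signs are
interpolated across; a profile that never changes sign raises, e.g. when no
water group is present).

## Hydrogen bonds

A bond is counted when the minimum-image donor–acceptor distance satisfies
r(D···A) ≤ 0.35 nm and the H–D–A angle ≤ 30°. These are the conventional
geometric criteria of the MD analysis ecosystem; the angle convention
(H–D–A rather than D–H–A) and both cutoffs are config keys echoed into
every report, since unstated analysis conventions are the main obstacle to
reproducing screening numbers. The hydroxy group acts as donor and
acceptor; ester/amide carbonyl oxygens accept only. Detection uses a
periodic cell list and iterates over whichever side (donors or acceptors)
is smaller; it is exactly set-equal to the exhaustive O(N²) search, which
the acceptance suite verifies on 50 random 500-atom configurations. For
boxes smaller than three cells per dimension the code falls back to the
exhaustive search, which is always exact.

"Per molecule" means summed over the ligand copies and divided by the
number of copies, per frame.

## SASA

Shrake–Rupley dot surfaces with probe radius 0.14 nm, 960 dots per atomic
sphere, and a Bondi-type vdW radii table (all config, all echoed). Dots are
a deterministic Fibonacci spiral lattice, so areas are seed-free and
exactly reproducible; doubling the dot count is a pure refinement. Occluder
distances use the minimum image; an atom never occludes itself. For the
group statistics the occluder set is *every* other atom in the system —
lipids, water, ions, the rest of the molecule, and by default the other
ligand copies (switchable), since the quantity of interest is the
availability of the group in the membrane context. Quadrature error against
the closed-form sphere is zero for an isolated atom (all dots free) and
≲ 3 single-dot areas across a two-sphere distance sweep; the tests allow 5.

## Block statistics

H-bond and SASA series are split into 5 contiguous equal-length blocks
(frames dropped from the end if the count is not divisible, and reported);
the statistic is the grand mean with the sample SD (ddof = 1) of the block
means as the error bar. With the default generator timing — 200 frames at
7.5 ns spacing, a 1500 ns span — the blocks are 300 ns each.

## Ligand clusters

Two copies are adjacent when their minimum inter-atomic minimum-image
distance is ≤ 0.4 nm (single linkage; the published observation of
transient clusters names no criterion, so the cutoff is config). Clusters
are connected components; the time series reports the fraction of frames
containing any cluster of size ≥ 2 and the mean largest cluster size.

## Synthetic generator: what it emulates and what it does not

The generator reproduces, at reduced scale, the *composition and geometry*
of the assay-mimicking study system: a bilayer patch (pseudo-lipids as
3-bead chains with head beads at ±2.0 nm), two water slabs, K⁺ ions, and
four rigid toy-ligand copies placed on laterally separated sites, half per
leaflet. Defaults: 16 lipids, 400 waters, 8 K⁺, 4 copies in a 4 × 4 × 7 nm
box, 200 frames at 7.5 ns (1500 ns span); full-scale counts (128 lipids,
6400 waters, 128 K⁺) sit behind `paper_scale()`. Reference scenarios draw
tilt/depth from Normal distributions matching the control populations
(hmi_like: μθ = 30°, σ = 8°, μd = 1.65 nm, σ = 0.08 nm; pyr_like:
μθ = 150°, μd = 1.00 nm), flip 5 % of draws to emulate the small opposing
populations, inject Bernoulli hydrogen-bond events at ideal geometry
(r = 0.30 nm, angle 0°, hmi_like rate 0.8), and form a transient dimer in
20 % of hmi_like frames. Ligand depths are placed relative to the realized
lipid COM of each frame, so the recorded ground truth is exact rather than
jittered by lipid placement noise.

Frames are i.i.d. draws, not dynamics. Consequences for interpreting green
tests: they validate the *measurement* chain (geometry, binning,
detection, statistics) against exact ground truth, and say nothing about
force fields, sampling, or equilibration of real trajectories. Two further
non-emulated features matter:

* the membrane core is far sparser than a real one, so absolute SASA
  values are much larger than experimental-scale numbers and the
  exposed-vs-buried SASA contrast of a real membrane is not reproduced
  (the ordering property is tested with constructed occluder cages
  instead);
* block SDs reflect independent frames, not the autocorrelated dynamics
  that block averaging is designed for; the scheme's arithmetic (block
  length, remainder handling, SD of block means) is what is being tested.

## Numerical and degenerate-input choices

* GRO I/O is fixed-point at the format's 3-decimal (nm) precision;
  write→read is exactly idempotent. Triclinic boxes are rejected, not
  skewed. Velocities are parsed and discarded.
* Masses/radii are inferred from atom names (leading alphabetic
  characters, two-letter symbols first), overridable per name — GRO
  carries neither.
* NDX groups are 1-based on disk, 0-based in memory, order-preserving;
  duplicate indices are an error except in the documented pair-list groups
  (`*_donors`, `*_bonds`) that serialise (D,H) and bond pairs.
* Empty sample streams give empty heat maps (n_samples = 0), but the mode
  and verdict of an empty map are errors; an empty selection gives an
  all-zero density profile.
* The equilibration trim is a duration with a default of 1/16 of the span
  (100 ns of a 1.6 μs trajectory); the report always records total,
  discarded and analyzed spans, which must sum exactly.
* Analysis sizes in the test and acceptance runs (reduced water counts,
  40–5000 frames) are chosen to give the statistical power each check
  needs — e.g. 20 000 samples for one-bin mode recovery — while keeping
  the suite fast.

## Known limitations

Single flat bilayer only; no instantaneous local normals, lipid order
parameters, electron densities, H-bond lifetimes, or cluster kinetics.
Compressed trajectory formats are not read natively (adapter seam in
`trajio`). The classifier is a mode-cell rule with fixed thresholds — it is
a screening heuristic, not a free-energy statement.
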