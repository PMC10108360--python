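# c1screen

Post-processing and screening analysis for molecular-dynamics trajectories of
protein kinase C (PKC) agonist candidates in lipid bilayers.

Diacylglycerol (DAG) mimetics activate PKC by binding its C1 domain at the
membrane surface, and a candidate's prospects depend on how it sits in the
bilayer *before* the protein arrives: a promising ligand keeps its
hydroxymethyl group pointed toward the lipid–water interface and available
for hydrogen bonding, while a poor one (e.g. one locked by an intramolecular
hydrogen bond) flips over and sinks toward the membrane core. `c1screen`
quantifies this behavior from multi-frame trajectories of a bilayer patch
with several ligand copies, and classifies each candidate against
positive-control-like ("correct") and negative-control-like ("incorrect")
orientation populations.

## What it computes

For each ligand copy in each frame, with the membrane normal fixed to the
box *z* axis:

* **tilt angle** θ = ∠(**a**, **n̂**), where **a** = COM(axis head) −
  COM(axis tail) is the ligand's central axis vector (core ring → hydroxy
  oxygen by default) and **n̂** is the *outward* normal of the leaflet
  hosting the hydroxy group (+z upper, −z lower);
* **hydroxy depth** d = |z(OH COM) − z(bilayer COM)|, leaflet-folded and
  minimum-image.

From the (θ, d) samples it builds a 2D population heat map (default 5° ×
0.05 nm bins), finds the modal cell, and labels the candidate **correct**
(mode θ ≤ 60° and d ≥ 1.4 nm), **incorrect** (θ ≥ 120° and d ≤ 1.2 nm) or
**ambiguous**. Around that core readout it provides:

* partial mass-density profiles along the normal (kg·m⁻³, per selection
  group, per-frame recentered on the bilayer COM) with lipid–water
  interface localization;
* geometric hydrogen-bond counts per molecule (r(D···A) ≤ 0.35 nm and
  H–D–A ≤ 30° by default) for the hydroxy (OH) and ester/amide (OO/NO)
  groups against water and lipid, as time-block averages (5 contiguous
  equal blocks, SD of block means as the error);
* Shrake–Rupley dot-surface SASA (probe 0.14 nm, 960 deterministic
  Fibonacci dots per sphere, minimum-image occlusion) of the same groups,
  with the same block statistics;
* transient ligand-cluster detection (single-linkage over minimum
  inter-atomic distances, default cutoff 0.4 nm).

A synthetic-trajectory generator emulates the assay-mimicking study system —
an anionic SDPS-like bilayer patch with water, K⁺ counterions, and four
ligand copies placed with lateral separation — at reduced scale, drawing
tilt/depth per frame from configured distributions and injecting
ideal-geometry hydrogen-bond events and dimer episodes with exact ground
truth, so the whole pipeline is testable without running MD.

## Worked example

```bash
c1screen generate --scenario hmi_like --seed 1 --n-frames 40 --out demo
c1screen orient demo.gro demo.ndx
```

prints

```json
{
  "mode_theta": 27.5,
  "mode_depth": 1.6750000000000003,
  "label": "correct",
  "secondary_population_fraction": 0.0375
}
```

i.e. the dominant population sits at θ ≈ 27.5° with the hydroxy group
1.675 nm from the bilayer center — near the lipid headgroups, axis pointing
out of the membrane — so the candidate is classified "correct"; 3.75 % of
samples are in the flipped (θ > 90°) population. The full pipeline (heat
map, densities, H-bonds, SASA, clusters, JSON/CSV/PNG artifacts) runs from
a YAML config:

```bash
c1screen screen screen.yaml --out results_dir
```

with exit status 0 when every candidate is "correct", 1 otherwise, 2 on
stage errors.

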