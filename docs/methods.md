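# Methods

This note documents the models and procedures implemented in `lipsite`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not demonstrate about real trajectories.

## Binding-event model

A binding site is a cavity centre (either a fixed point or the per-frame
centre of mass of a configured bead selection, unit bead masses by default)
plus two radii. Per frame, each lipid's distance to the centre is the minimum
over its beads of the minimum-image distance in the orthorhombic box. States
follow a two-threshold (hysteresis) machine:

* outside → inside when d ≤ r_on (default **1.8 nm**),
* inside stays inside while d ≤ r_off (default **3.5 nm**),
* inside → outside when d > r_off,
* the state at frame 0 is inside iff d ≤ r_on.

The buffer radius is the smoothing: a lipid rattling around the cavity rim
crosses r_on many times but r_off rarely, so one physical visit yields one
event instead of many. Maximal runs of "inside" become events; runs touching
either trajectory end are flagged truncated, and an event's duration is
(number of inside frames) × frame interval. Truncated events are **included**
in summaries by default (a censoring switch excludes them); with dwells much
shorter than a replica this biases means by only a few percent, and the bias
direction (down) is the same for all types, largely cancelling in ratios.

## Residence-time statistics

Event durations are summarized per lipid type. The headline comparison is
mean(CDL durations) / mean(all non-CDL durations pooled); per-type ratios are
also reported. Uncertainty is a percentile bootstrap of the event-level mean
(resampling events, not frames, with replacement at the original sample size;
default 10 000 resamples, 90% interval, seeded). Each type is compared with
cardiolipin by a two-sided Mann-Whitney U test: the exact null distribution
when n_x + n_y ≤ 12 and there are no ties, otherwise the normal approximation
with midranks, tie correction and continuity correction (delegated to
`scipy.stats.mannwhitneyu`; an enumeration oracle in the test suite verifies
both branches). Events are pooled across replicas by default; a per-replica
breakdown is available from the event table.

## Transition probabilities

For lag τ (a multiple of the frame interval) every ordered pair of frames
(k, k+τ) of every lipid is classified as enter (o→i), remain (i→i), exit
(i→o) or stay out (o→o); pairs never span replica boundaries. Counts are
normalized **within each lipid type**, so the four curves of a type sum to 1
and curves of rare and abundant types are directly comparable. A "pooled"
mode instead divides by the pair total summed over all types; it is provided
because the two normalizations answer different questions (per-type: "what
does a CDL molecule do over τ?"; pooled: "what fraction of all pair events is
a CDL entry?") and the pooled form matches a literal reading of the summed
equation. Per-type is the default because the per-type curves are the
quantity the comparisons need. Undefined ratios (no lipids of a type, or a
zero denominator) are reported as missing, never as 0. The default τ grid is
logarithmic, 24 points over 1–3000 ns, snapped to frame-interval multiples
with duplicates removed.

## Synthetic membrane generator

The generator replaces a coarse-grained MD engine with the minimal stochastic
process that has the same *statistics* the analyses consume:

* **Composition** — 45% POPC / 30% POPE / 20% CDL / 5% POPA by default,
  realized by largest-remainder rounding (ties broken by declaration order).
* **Diffusion** — each lipid is one bead performing an independent 2D random
  walk with per-axis displacement variance 2DΔt under periodic wrapping.
  Default D = 0.05 nm²/ns for every type, in the range of lateral diffusion
  coefficients of coarse-grained phospholipids.
* **Trapping** — a lipid entering the capture disk (default radius 1.5 nm)
  is trapped: its position jitters uniformly within half the capture radius
  and each frame it escapes with probability 1 − exp(−kΔt), where k is the
  per-type escape hazard. Dwell times are therefore geometric with mean
  ≈ 1/k + Δt/2, i.e. exponential up to time discretization — a closed-form
  ground truth. Defaults k(CDL) = 0.01 /ns and k(others) = 0.025 /ns plant
  mean dwells of 100 vs 40 ns, a 2.5× cardiolipin advantage well inside a
  4 μs replica.
* **Re-insertion** — an escaped lipid is placed 0.1 nm outside the capture
  radius in a uniform random direction, keeping re-entry diffusion-limited.
* **Scale** — three replicas of 4000 frames × 1 ns (the frame interval is a
  free choice exposed in config). The default patch is 25 × 25 nm with 400
  lipids (~0.64 lipids/nm², about one leaflet at typical area per lipid);
  the full-scale system (8624 lipids, 50 × 50 nm) is expressible in config
  but the analyses are exercised at desk scale.
* **Reproducibility** — one seeded generator per replica (seed + replica
  index): replicas are independent yet the ensemble is bitwise reproducible.
* An optional rigid 3-bead lipid mode (0.3 nm spacing, random fixed
  orientation) exercises the min-over-beads distance code path.

What the generator does **not** emulate: forces, lipid–lipid interactions,
finite lipid size or excluded volume, solvent, membrane undulations, any
thermostat/barostat physics, and spatially structured binding free-energy
landscapes. Passing recovery tests therefore show that the *analysis chain*
is unbiased for Markovian trapping with known rates — not that any particular
force field or real membrane behaves this way.

**Ground-truth protocol.** Quantitative recovery tests analyse generator
output with r_on = r_off = capture radius, so the labelled state coincides
with the generator's trapped state and measured dwells follow the planted
escape law. With the default radii (1.8/3.5 nm) the re-inserted lipid sits
inside the hysteresis band, so successive trapping episodes merge into longer
events; the dual-cutoff analysis of the default ensemble accordingly reports
longer mean residences (and a slightly smaller CDL ratio) than the planted
dwell law — behaviour of the smoothing itself, exercised qualitatively.

## Structure metrics

* **SASA** — Shrake–Rupley with a deterministic Fibonacci sphere lattice
  (default 960 points, probe 1.4 Å); per-atom area is the accessible point
  fraction × 4π(r_vdw + probe)². Radii are Bondi van der Waals values
  (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å, plus common ions) from
  one documented table. Hydrogens absent from a model are simply absent
  (united-atom treatment), not reconstructed.
* **Buried interface area** — BSA = [SASA(A) + SASA(B) − SASA(A∪B)] / 2, the
  per-side (PISA-style) convention; the unhalved ΔSASA is always reported
  alongside because published figures use both conventions.
* **Lipid census** — counts distinct het residues (one per residue identity,
  altlocs collapse) whose name is in a configurable set; the default set
  covers cardiolipin (CDL/CL/CDN) and common phospholipid codes and excludes
  water and detergents.
* **Dimer angle** — each monomer's rotation axis is the first principal
  component of its selected coordinates (recommended selection: c-ring plus
  central stalk), oriented away from the midpoint between the two selections;
  the angle is the arccos of the unit-axis dot product. A selection whose top
  two principal values agree within 5% has no well-defined axis and is
  rejected. This principal-axis construction is this package's
  operationalization of a "dimer angle"; other axis definitions can differ
  by a few degrees.
* **RDF and distances** — minimum-image pair histograms normalized by the
  ideal-gas expectation, with 2D annulus normalization for planar systems
  (z-extent < 1e-6 nm) and 3D shells otherwise; `pair_min_distance` produces
  exactly the per-lipid distance series the state machine consumes.

## Numerical and design choices

* Structures are Å (PDB convention), trajectories and all kinetics are nm;
  conversion only at I/O boundaries.
* Altloc resolution: highest occupancy wins, first occurrence on ties.
* Elements missing from a file are inferred from atom names; an unknown
  element is an error naming the atom.
* τ values must be exact frame multiples; the default grid snaps and
  deduplicates rather than interpolating.
* Bootstrap and pipeline runs are deterministic given the config seed; output
  tables carry a provenance header (version, config hash, seed) and identical
  configs produce byte-identical files.
* Degenerate inputs fail loudly: empty samples, empty selections, empty
  cavity selections, zero escape rates (infinite dwell) and τ beyond the
  replica length all raise with a description.

## Limitations

* Single binding site; no multi-site bookkeeping or site discovery.
* The generator's trapping is memoryless by construction; analyses of real
  trajectories with non-exponential dwells are summarized correctly, but the
  generator cannot emulate them.
* SASA neighbour search assumes no periodicity (appropriate for deposited
  models); trajectory metrics assume orthorhombic boxes.
* Entity counting groups chains by identical polymer sequence, which matches
  deposition practice but will over-count entities if a deposition splits one
  polypeptide across chains with different residue subsets.
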