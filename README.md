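# lipsite

Lipid binding-site kinetics and structural metrics for membrane-protein
systems — built around the analyses used to characterize cardiolipin binding
in a mitochondrial ATP synthase dimer from coarse-grained membrane
trajectories and deposited coordinate models.

## What it computes

**Binding kinetics** (for anyone with per-frame bead positions of labelled
lipids and a binding-pocket definition):

* Dual-cutoff (hysteresis) event detection: a lipid starts a binding event
  when any of its beads comes within the entry radius r_on = 1.8 nm of the
  cavity centre of mass and stays bound until it leaves the r_off = 3.5 nm
  buffer, which suppresses rim flicker.
* Residence-time summaries per lipid type: means, 90% percentile-bootstrap
  confidence intervals over events, two-sided Mann-Whitney U tests of each
  type against cardiolipin (CDL), and the CDL / pooled-others mean ratio.
* Lag-dependent transition probabilities: for each type j and lag τ, the
  four probabilities ρ(o→i), ρ(i→i), ρ(i→o), ρ(o→o) of entering, remaining
  in, exiting, and staying out of the site over frame pairs (k, k+τ),
  τ = 1–3000 ns by default. For every defined (j, τ) they sum to 1.

**Structure metrics** (for PDB/mmCIF models): Shrake–Rupley SASA on a
deterministic Fibonacci lattice, buried interface area
BSA = [SASA(A)+SASA(B)−SASA(A∪B)]/2 between two selections, a lipid census
over het residues, the dimer angle between two monomers' principal axes, and
RDF / minimum-distance curves under periodic boundaries.

**Synthetic membrane generator**: a seeded 2D diffusion-and-trapping process
(default 45% POPC / 30% POPE / 20% CDL / 5% POPA, three replicas of 4 μs at
1 ns frames) with per-type exponential escape rates, so the mean residence
time of each type is exactly 1/escape_rate — a closed-form ground truth the
whole analysis chain is validated against. See `docs/methods.md` for the
model details and what the generator does and does not emulate.

## Worked example

```sh
python analysis/02_binding_kinetics.py
```

runs the reference-condition synthetic ensemble (400 lipids, 3 × 4 μs, pocket
escape rates 0.01 /ns for CDL vs 0.025 /ns for the others) through the full
kinetics chain and prints:

```
== dual-cutoff analysis (1.8 / 3.5 nm) ==
events: 2452
  CDL   mean residence    404.6 ns
  POPA  mean residence    193.8 ns
  POPC  mean residence    183.7 ns
  POPE  mean residence    186.1 ns
CDL / pooled-others mean ratio: 2.19
== ground-truth recovery (r_on = r_off = capture radius) ==
  CDL   n= 1484  mean    96.5 ns (90% CI    92.5-  100.5)  truth  100.0 ns  p_vs_CDL=1.00e+00
  POPA  n=  401  mean    39.7 ns (90% CI    36.5-   43.0)  truth   40.0 ns  p_vs_CDL=1.17e-40
  POPC  n= 4355  mean    39.9 ns (90% CI    38.9-   40.9)  truth   40.0 ns  p_vs_CDL=7.89e-139
  POPE  n= 2883  mean    41.0 ns (90% CI    39.8-   42.3)  truth   40.0 ns  p_vs_CDL=1.19e-117
recovered ratio 2.40 vs ground truth 2.50
```

Reading this: with radii matched to the generator's pocket, every type's
mean dwell recovers its planted 1/escape_rate (truth column) within its 90%
CI, the Mann-Whitney p-values separate every other type from cardiolipin,
and the CDL-vs-others ratio recovers the planted 2.5× within sampling error.
The dual-cutoff block above it shows what the 1.8/3.5 nm smoothing does to
the same trajectories: visits merge into longer events (the buffer is the
point), while cardiolipin's relative enrichment persists.

The other drivers follow the same pattern: `01_simulate_membrane.py` writes
the ensemble as standard GRO files plus a lipid-topology table,
`03_transition_probabilities.py` writes the ρ curves (per-type and pooled
normalization) and reports that CDL leads ρ(i→i) at every lag, and
`04_structure_metrics.py` runs census / dimer-angle / buried-area / SASA on
constructed fixtures with known answers.

There is also a CLI over the same pipeline:

```sh
lipsite all --config configs/synthetic_default.yaml
lipsite structure --model your_model.cif --output-dir results/structure
```

To run the structure metrics on deposited coordinate files (e.g. the
E. gracilis ATP synthase dimer, PDB 6TDU–6TE0, or yeast 6B2Z for
comparison), download them to `data/deposited/` and adapt
`configs/structure_deposited.yaml`, which documents the intended rotor /
stator / axis selections.

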