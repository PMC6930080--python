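#!/usr/bin/env python
"""Binding-event detection and residence-time statistics on the synthetic membrane.

Runs the dual-cutoff (1.8 nm entry / 3.5 nm buffer) event detector over the
reference-condition ensemble, summarizes residence times per lipid type with 90%
bootstrap intervals and Mann-Whitney comparisons against cardiolipin, and —
as a ground-truth check — repeats the analysis with entry radius = exit
radius = the generator's 1.5 nm capture radius, where the mean dwell of each
type must recover 1/escape_rate.

Tables land in results/binding_kinetics/.
"""

from pathlib import Path

import numpy as np

from lipsite import (
    BindingSite,
    RunConfig,
    analytic_residence,
    extract_events,
    residence_summary,
    run_pipeline,
    simulate_ensemble,
    state_series,
)
from lipsite.synthetic import allocate_composition

ROOT = Path(__file__).resolve().parent.parent
SEED = 1


def main() -> None:
    outdir = ROOT / "results" / "binding_kinetics"
    cfg = RunConfig.from_dict(
        {"mode": "synthetic", "seed": SEED, "output_dir": str(outdir)}
    )
    report = run_pipeline(cfg)
    print("== dual-cutoff analysis (1.8 / 3.5 nm) ==")
    print(f"events: {report['n_events']}")
    for t, m in sorted(report["mean_residence_ns"].items()):
        print(f"  {t:5s} mean residence {m:8.1f} ns")
    print(f"CDL / pooled-others mean ratio: {report['ratio_CDL_vs_others']:.2f}")

    # ground-truth recovery with radii matched to the pocket
    syn = cfg.raw["synthetic"]
    comp = allocate_composition(int(syn["n_lipids"]), syn["composition"])
    params = cfg.kinetic_params()
    traj = simulate_ensemble(params, comp)
    site = BindingSite(
        center=np.asarray(syn["pocket_center"], dtype=float),
        r_on=params.capture_radius,
        r_off=params.capture_radius,
    )
    events = extract_events(state_series(traj, site), traj.lipids)
    summary = residence_summary(events, traj.lipid_types, seed=SEED)
    truth = analytic_residence(params)
    print("== ground-truth recovery (r_on = r_off = capture radius) ==")
    for t, ts in sorted(summary.per_type.items()):
        lo, hi = ts.ci90
        print(
            f"  {t:5s} n={ts.n_events:5d}  mean {ts.mean_residence:7.1f} ns "
            f"(90% CI {lo:7.1f}-{hi:7.1f})  truth {truth[t]:6.1f} ns  "
            f"p_vs_CDL={ts.p_vs_CDL:.2e}"
        )
    truth_ratio = truth["CDL"] / np.mean([truth[t] for t in truth if t != "CDL"])
    print(
        f"recovered ratio {summary.ratio_CDL_vs_others:.2f} "
        f"vs ground truth {truth_ratio:.2f}"
    )
    print(f"tables: {outdir}/")


if __name__ == "__main__":
    main()
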