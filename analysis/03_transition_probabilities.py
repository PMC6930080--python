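#!/usr/bin/env python
"""Lag-dependent transition probabilities of pocket occupancy per lipid type.

Computes ρ(o→i), ρ(i→i), ρ(i→o), ρ(o→o) over a log grid of lags τ = 1-3000 ns
for the reference-condition synthetic ensemble and reports which lipid type
dominates occupancy at long lags (the generator plants a 2.5x dwell advantage
for cardiolipin, so CDL should lead ρ(i→i) at every τ).

The long-format curve table lands in results/transition_probabilities/.
"""

from pathlib import Path

import numpy as np

from lipsite import (
    BindingSite,
    RunConfig,
    default_tau_grid,
    extract_events,
    probability_curves,
    simulate_ensemble,
    state_series,
    write_table,
)
from lipsite.synthetic import allocate_composition

ROOT = Path(__file__).resolve().parent.parent
SEED = 1


def main() -> None:
    cfg = RunConfig.from_dict({"mode": "synthetic", "seed": SEED})
    syn = cfg.raw["synthetic"]
    comp = allocate_composition(int(syn["n_lipids"]), syn["composition"])
    traj = simulate_ensemble(cfg.kinetic_params(), comp)
    states = state_series(traj, cfg.binding_site())
    grid = default_tau_grid(traj.frame_interval)
    curves = probability_curves(states, grid, traj.types_of_lipids(), traj.lipid_types)
    pooled = probability_curves(
        states, grid, traj.types_of_lipids(), traj.lipid_types, mode="pooled"
    )

    outdir = ROOT / "results" / "transition_probabilities"
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(curves.to_frame(), outdir / "curves_per_type.tsv",
                header_comments=[f"seed {SEED}", "normalization per lipid type"])
    write_table(pooled.to_frame(), outdir / "curves_pooled.tsv",
                header_comments=[f"seed {SEED}", "normalization pooled over types"])

    print(f"tau grid: {len(grid)} lags from {grid[0]:.0f} to {grid[-1]:.0f} ns")
    for i in (0, len(grid) // 2, len(grid) - 1):
        tau = grid[i]
        ranking = sorted(
            ((curves.rho[t]["ii"][i], t) for t in traj.lipid_types
             if not np.isnan(curves.rho[t]["ii"][i])),
            reverse=True,
        )
        lead = ", ".join(f"{t}={v:.3f}" for v, t in ranking[:2])
        print(f"  tau {tau:6.0f} ns: highest rho(i->i): {lead}")
    n_events = len(extract_events(states, traj.lipids))
    print(f"(from {n_events} binding events; tables in {outdir}/)")


if __name__ == "__main__":
    main()
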