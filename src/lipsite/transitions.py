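"""Lag-dependent transition probabilities of binding-site occupancy.

For each lipid type j and lag τ, every frame pair (k, k+τ) of every lipid of
that type is classified by its ordered state pair: enter (o→i), remain (i→i),
exit (i→o) or stay out (o→o).  Dividing each count by the total number of
pairs yields four probabilities ρ that sum to one — a model-free fingerprint
of how persistently each lipid type occupies the site across timescales
(τ defaults to a log grid over 1–3000 ns).

Two normalization modes exist: "per_type" (default) normalizes within each
lipid type so the curves of rare and abundant types are comparable, while
"pooled" divides every count by the pair total summed over all types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import IN, OUT, StateSeries

__all__ = [
    "TransitionCounts",
    "TransitionProbabilityCurve",
    "count_transitions",
    "probability_curves",
    "default_tau_grid",
]

KINDS = ("oi", "ii", "io", "oo")


@dataclass
class TransitionCounts:
    """Pair counts N_oi, N_ii, N_io, N_oo per lipid type at one lag."""

    tau: float  # ns
    counts: dict[str, dict[str, int]]  # type -> kind -> count

    def total(self, type_label: str) -> int:
        return sum(self.counts[type_label].values())


@dataclass
class TransitionProbabilityCurve:
    """ρ_oi, ρ_ii, ρ_io, ρ_oo per lipid type over a τ grid (NaN = undefined)."""

    tau_grid: np.ndarray  # ns
    rho: dict[str, dict[str, np.ndarray]]  # type -> kind -> (n_tau,)
    mode: str = "per_type"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, kinds in self.rho.items():
            for i, tau in enumerate(self.tau_grid):
                rows.append(
                    {
                        "type": t,
                        "tau_ns": float(tau),
                        "rho_oi": kinds["oi"][i],
                        "rho_ii": kinds["ii"][i],
                        "rho_io": kinds["io"][i],
                        "rho_oo": kinds["oo"][i],
                    }
                )
        return pd.DataFrame(rows)


def default_tau_grid(
    frame_interval: float, tau_min: float = 1.0, tau_max: float = 3000.0, n: int = 24
) -> np.ndarray:
    """Logarithmic τ grid (ns) snapped to frame-interval multiples, deduplicated."""
    raw = np.geomspace(max(tau_min, frame_interval), tau_max, n)
    snapped = np.maximum(np.round(raw / frame_interval), 1) * frame_interval
    return np.unique(snapped)


def count_transitions(
    states: StateSeries, tau: float, type_labels: list[str] | np.ndarray = None
) -> TransitionCounts:
    """Count ordered state pairs (k, k+τ) per lipid type, accumulated over replicas.

    ``type_labels`` gives the per-lipid type (aligned with the state rows);
    when omitted all lipids share the label "all".  τ must be a positive
    multiple of the frame interval and shorter than every replica.
    """
    dt = states.frame_interval
    m = tau / dt
    if tau <= 0 or abs(m - round(m)) > 1e-9:
        raise ValueError(f"tau={tau} ns is not a positive multiple of the frame interval {dt} ns")
    m = int(round(m))
    out: dict[str, dict[str, int]] = {}
    for s in states.states:
        n_lip, n_frames = s.shape
        if m >= n_frames:
            raise ValueError(f"tau={tau} ns is not shorter than the replica ({n_frames} frames)")
        labels = (
            np.asarray(type_labels) if type_labels is not None else np.array(["all"] * n_lip)
        )
        if labels.size != n_lip:
            raise ValueError("type_labels length does not match the number of lipids")
        a, b = s[:, :-m], s[:, m:]
        for t in np.unique(labels):
            rows = labels == t
            aa, bb = a[rows], b[rows]
            rec = out.setdefault(t, {k: 0 for k in KINDS})
            rec["oi"] += int(((aa == OUT) & (bb == IN)).sum())
            rec["ii"] += int(((aa == IN) & (bb == IN)).sum())
            rec["io"] += int(((aa == IN) & (bb == OUT)).sum())
            rec["oo"] += int(((aa == OUT) & (bb == OUT)).sum())
    return TransitionCounts(tau=tau, counts=out)


def probability_curves(
    states: StateSeries,
    tau_grid: np.ndarray,
    type_labels: list[str] | np.ndarray = None,
    lipid_types: list[str] | None = None,
    mode: str = "per_type",
) -> TransitionProbabilityCurve:
    """Transition probabilities over a τ grid.

    mode="per_type": ρ(event | j, τ) = N_j,event / Σ_event N_j,event — the
    four curves of each type sum to one.  mode="pooled": the denominator sums
    the pair totals over all types as well.  Types with no lipids (or τ with
    no valid pairs) are reported as NaN, never as zero.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size == 0:
        raise ValueError("empty tau grid")
    if mode not in ("per_type", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    if type_labels is None:
        present: list[str] = ["all"]
    else:
        present = list(dict.fromkeys(np.asarray(type_labels)))
    all_types = list(lipid_types) if lipid_types is not None else present
    rho = {t: {k: np.full(tau_grid.size, np.nan) for k in KINDS} for t in all_types}
    for i, tau in enumerate(tau_grid):
        tc = count_transitions(states, tau, type_labels)
        pooled_total = sum(tc.total(t) for t in tc.counts)
        for t in all_types:
            if t not in tc.counts:
                continue
            denom = pooled_total if mode == "pooled" else tc.total(t)
            if denom == 0:
                continue
            for k in KINDS:
                rho[t][k][i] = tc.counts[t][k] / denom
    return TransitionProbabilityCurve(tau_grid=tau_grid, rho=rho, mode=mode)
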