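"""Dual-cutoff binding-event detection and residence-time statistics.

A lipid begins a binding event when any of its beads comes within the entry
radius ``r_on`` (default 1.8 nm) of the cavity centre of mass, and remains
bound until it leaves a larger buffer radius ``r_off`` (default 3.5 nm).  The
two-radius hysteresis smooths intermittent excursions at the cavity rim, so a
brief flicker across the entry radius does not split one visit into many
events.  Event durations are summarized per lipid type with percentile
bootstrap confidence intervals and Mann-Whitney U comparisons against
cardiolipin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .io_formats import TrajectoryEnsemble

__all__ = [
    "BindingSite",
    "StateSeries",
    "BindingEvent",
    "ResidenceSummary",
    "TypeSummary",
    "min_distance_series",
    "state_series",
    "states_from_distances",
    "extract_events",
    "residence_summary",
    "bootstrap_ci",
    "mann_whitney_u",
]

OUT, IN = 0, 1  # state labels o / i


@dataclass
class BindingSite:
    """Binding-pocket definition: cavity centre rule plus entry/exit radii (nm).

    ``center`` is either a fixed point (2- or 3-vector, nm) or a bead-index
    selection whose per-frame centre of mass defines the cavity centre;
    ``masses`` optionally weights that centre (unit masses by default, as
    coarse-grained beads are near-equal mass).
    """

    center: np.ndarray | Sequence[int] | Callable = None
    r_on: float = 1.8
    r_off: float = 3.5
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0 < self.r_on <= self.r_off):
            raise ValueError("need r_off >= r_on > 0")

    def center_per_frame(self, replica_positions: np.ndarray) -> np.ndarray:
        """(n_frames, 3) cavity centre for one replica."""
        n_frames = replica_positions.shape[0]
        if callable(self.center):
            return np.asarray([self.center(replica_positions[f]) for f in range(n_frames)])
        arr = np.asarray(self.center)
        if arr.ndim == 1 and arr.dtype.kind == "f" and arr.size in (2, 3):
            # a float vector is a fixed cavity point; int arrays are bead indices
            c = np.zeros(3)
            c[: arr.size] = arr
            return np.tile(c, (n_frames, 1))
        idx = np.asarray(self.center, dtype=int)
        if idx.size == 0:
            raise ValueError("empty cavity selection")
        sel = replica_positions[:, idx, :]
        if self.masses is not None:
            w = np.asarray(self.masses, dtype=float)
            return (sel * w[None, :, None]).sum(axis=1) / w.sum()
        return sel.mean(axis=1)


@dataclass
class StateSeries:
    """Per-replica (n_lipids, n_frames) arrays of inside(1)/outside(0) labels."""

    states: list[np.ndarray]
    frame_interval: float  # ns

    def __post_init__(self) -> None:
        for s in self.states:
            u = np.unique(s)
            if not np.all(np.isin(u, [OUT, IN])):
                raise ValueError("state labels must be o(0) or i(1)")

    @property
    def n_replicas(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class BindingEvent:
    """One smoothed residence interval of one lipid (closed frame interval)."""

    replica: int
    lipid_id: int
    type_label: str
    start_frame: int
    end_frame: int
    duration: float  # ns
    truncated_start: bool
    truncated_end: bool


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention along each orthorhombic box axis."""
    finite = np.isfinite(box)
    out = delta.copy()
    out[..., finite] -= box[finite] * np.round(delta[..., finite] / box[finite])
    return out


def min_distance_series(traj: TrajectoryEnsemble, site: BindingSite) -> list[np.ndarray]:
    """Per replica, the (n_lipids, n_frames) min-over-beads distance to the cavity centre."""
    out = []
    bead_idx = np.concatenate([list(l.bead_indices) for l in traj.lipids])
    group_offsets = np.cumsum([0] + [len(l.bead_indices) for l in traj.lipids])[:-1]
    for rep in traj.replicas:
        centers = site.center_per_frame(rep.positions)  # (F, 3)
        if centers.shape[0] != rep.n_frames:
            raise ValueError("cavity centre rule returned wrong number of frames")
        delta = rep.positions[:, bead_idx, :] - centers[:, None, :]  # (F, B, 3)
        if np.allclose(rep.boxes, rep.boxes[0]):
            delta = minimum_image(delta, rep.boxes[0])
        else:
            delta = np.stack(
                [minimum_image(delta[f], rep.boxes[f]) for f in range(rep.n_frames)]
            )
        dist = np.sqrt((delta**2).sum(axis=-1))  # (F, B)
        dmin = np.minimum.reduceat(dist, group_offsets, axis=1)  # (F, n_lipids)
        out.append(np.ascontiguousarray(dmin.T))
    return out


def states_from_distances(
    distances: np.ndarray, r_on: float, r_off: float
) -> np.ndarray:
    """Hysteresis labelling of a (..., n_frames) distance array.

    o→i when d ≤ r_on; i stays i while d ≤ r_off; i→o when d > r_off.  The
    initial state is i iff the first distance is ≤ r_on.
    """
    d = np.atleast_2d(np.asarray(distances, dtype=float))
    n_frames = d.shape[-1]
    states = np.zeros(d.shape, dtype=np.int8)
    cur = (d[:, 0] <= r_on).astype(np.int8)
    states[:, 0] = cur
    for f in range(1, n_frames):
        enter = d[:, f] <= r_on
        stay = d[:, f] <= r_off
        cur = np.where(cur == IN, stay, enter).astype(np.int8)
        states[:, f] = cur
    if np.asarray(distances).ndim == 1:
        return states[0]
    return states


def state_series(traj: TrajectoryEnsemble, site: BindingSite) -> StateSeries:
    """Label every lipid in every frame as inside (i) or outside (o) the site."""
    dists = min_distance_series(traj, site)
    return StateSeries(
        states=[states_from_distances(d, site.r_on, site.r_off) for d in dists],
        frame_interval=traj.frame_interval,
    )


def extract_events(
    states: StateSeries, lipids: Sequence | None = None
) -> list[BindingEvent]:
    """Turn maximal runs of i into :class:`BindingEvent` records.

    Runs touching the first or last frame are flagged as truncated (the visit
    started before, or outlived, the trajectory).  ``lipids`` supplies type
    labels; without it every lipid is labelled "?".
    """
    dt = states.frame_interval
    events: list[BindingEvent] = []
    for rep_i, s in enumerate(states.states):
        n_lip, n_frames = s.shape
        for li in range(n_lip):
            row = s[li]
            padded = np.concatenate([[OUT], row, [OUT]])
            d = np.diff(padded)
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1) - 1
            for a, b in zip(starts, ends):
                if lipids is not None:
                    lid = lipids[li].lipid_id
                    lab = lipids[li].type_label
                else:
                    lid, lab = li, "?"
                events.append(
                    BindingEvent(
                        replica=rep_i,
                        lipid_id=lid,
                        type_label=lab,
                        start_frame=int(a),
                        end_frame=int(b),
                        duration=float((b - a + 1) * dt),
                        truncated_start=a == 0,
                        truncated_end=b == n_frames - 1,
                    )
                )
    return events


def bootstrap_ci(
    durations: Sequence[float],
    level: float = 0.90,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of ``durations``.

    Draws ``n_boot`` resamples with replacement of the original size and
    returns the (1±level)/2 percentiles of the resampled means.  Deterministic
    given ``seed``.
    """
    x = np.asarray(durations, dtype=float)
    if x.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = np.percentile(means, [50 * (1 - level), 50 * (1 + level)])
    return float(lo), float(hi)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided); returns (U for x, p).

    With ``method="auto"`` the exact null distribution is used when
    n_x + n_y ≤ 12 and the samples are tie-free, otherwise the normal
    approximation with midranks, tie correction and continuity correction.
    ``method`` may force ``"exact"`` or ``"asymptotic"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        combined = np.concatenate([x, y])
        tie_free = np.unique(combined).size == combined.size
        method = "exact" if (x.size + y.size <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class TypeSummary:
    """Residence-time summary of one lipid type."""

    type_label: str
    n_events: int
    mean_residence: float  # ns
    ci90: tuple[float, float]
    U_vs_CDL: float
    p_vs_CDL: float


@dataclass
class ResidenceSummary:
    """Per-type residence statistics plus the CDL-vs-others mean ratio."""

    per_type: dict[str, TypeSummary]
    ratio_CDL_vs_others: float  # nan when undefined (single type present)
    cdl_label: str
    per_type_ratio: dict[str, float] = field(default_factory=dict)


def residence_summary(
    events: Sequence[BindingEvent],
    lipid_types: Sequence[str],
    cdl_label: str = "CDL",
    include_truncated: bool = True,
    ci_level: float = 0.90,
    n_boot: int = 10_000,
    seed: int = 0,
) -> ResidenceSummary:
    """Summarize event durations per type and compare each type against CDL.

    The headline ratio is mean(CDL durations) / mean(all non-CDL durations
    pooled); per-type ratios are also reported.  Events truncated by the
    trajectory ends are included by default (``include_truncated=False``
    censors them).  The U statistic is reported for the type's sample against
    the CDL sample.
    """
    if not events:
        raise ValueError("no binding events to summarize")
    if include_truncated:
        kept = list(events)
    else:
        kept = [e for e in events if not (e.truncated_start or e.truncated_end)]
        if not kept:
            raise ValueError("all events are truncated; nothing to summarize")
    durations: dict[str, np.ndarray] = {
        t: np.array([e.duration for e in kept if e.type_label == t]) for t in lipid_types
    }
    cdl = durations.get(cdl_label, np.array([]))
    per_type: dict[str, TypeSummary] = {}
    per_type_ratio: dict[str, float] = {}
    for t in lipid_types:
        d = durations[t]
        if d.size == 0:
            continue
        ci = bootstrap_ci(d, level=ci_level, n_boot=n_boot, seed=seed)
        if t != cdl_label and cdl.size and d.size:
            u, p = mann_whitney_u(d, cdl)
        elif t == cdl_label and cdl.size:
            u, p = float(d.size * cdl.size / 2), 1.0
        else:
            u, p = float("nan"), float("nan")
        per_type[t] = TypeSummary(
            type_label=t,
            n_events=int(d.size),
            mean_residence=float(d.mean()),
            ci90=ci,
            U_vs_CDL=u,
            p_vs_CDL=p,
        )
        if t != cdl_label and cdl.size and d.size:
            per_type_ratio[t] = float(cdl.mean() / d.mean())
    others = np.concatenate(
        [durations[t] for t in lipid_types if t != cdl_label and durations[t].size]
        or [np.array([])]
    )
    if cdl.size and others.size:
        ratio = float(cdl.mean() / others.mean())
    else:
        ratio = float("nan")
    return ResidenceSummary(
        per_type=per_type,
        ratio_CDL_vs_others=ratio,
        cdl_label=cdl_label,
        per_type_ratio=per_type_ratio,
    )
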