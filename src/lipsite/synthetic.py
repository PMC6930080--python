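"""Synthetic coarse-grained membrane trajectories with a single binding pocket.

The generator emulates the statistical structure of a MARTINI-style bilayer
around a membrane-protein binding cavity: a four-component lipid mixture
(default 45% POPC / 30% POPE / 20% CDL / 5% POPA), free lateral diffusion in
a periodic patch, and one circular pocket that traps lipids and releases them
with a per-type exponential escape hazard.  Because dwell times are exponential
by construction, the mean residence time of a type is exactly
``1 / escape_rate`` — a closed-form ground truth for parameter-recovery tests.

It is a statistics generator, not a physics engine: there are no forces, no
solvent, no lipid-lipid interactions, and the membrane plane is strictly 2D
(an optional rigid 3-bead mode exists to exercise min-over-beads analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import LipidMolecule, Replica, TrajectoryEnsemble

__all__ = [
    "DEFAULT_FRACTIONS",
    "MembraneComposition",
    "KineticParams",
    "allocate_composition",
    "simulate_ensemble",
    "analytic_residence",
]

#: Default bilayer composition (fractions of lipid molecules).
DEFAULT_FRACTIONS: dict[str, float] = {"POPC": 0.45, "POPE": 0.30, "CDL": 0.20, "POPA": 0.05}


@dataclass(frozen=True)
class MembraneComposition:
    """Lipid-type fractions and the integer molecule counts realizing them."""

    fractions: dict[str, float]
    counts: dict[str, int]

    def __post_init__(self) -> None:
        total_frac = sum(self.fractions.values())
        if abs(total_frac - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total_frac}, not 1")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative lipid count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def allocate_composition(total: int, fractions: dict[str, float]) -> MembraneComposition:
    """Allocate ``total`` lipids to types by largest-remainder rounding.

    Each type first receives the floor of its quota ``total * fraction``; the
    leftover molecules go to the largest fractional remainders, ties broken by
    declaration order.  Deterministic.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    if any(f < 0 for f in fractions.values()):
        raise ValueError("negative fraction")
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labels = list(fractions)
    quotas = np.array([total * fractions[t] for t in labels])
    counts = np.floor(quotas + 1e-12).astype(int)
    remainders = quotas - counts
    short = total - int(counts.sum())
    # stable sort: descending remainder, declaration order breaks ties
    order = sorted(range(len(labels)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        counts[i] += 1
    return MembraneComposition(
        fractions=dict(fractions), counts={t: int(c) for t, c in zip(labels, counts)}
    )


@dataclass
class KineticParams:
    """Parameters of the diffusion-and-trapping generator.

    diffusion_coeff : nm²/ns per lipid type (lateral diffusion constant D).
    pocket_center   : (x, y) of the binding pocket, nm.
    capture_radius  : a lipid within this distance of the pocket center is
                      trapped; 0 disables trapping (free diffusion).
    escape_rate     : 1/ns per type; hazard of leaving the pocket, so the
                      per-frame escape probability is 1 − exp(−rate·Δt).
    box             : (Lx, Ly) of the periodic membrane patch, nm.
    n_frames        : frames per replica.
    frame_interval  : Δt between saved frames, ns.
    n_replicas      : number of independent replicas (generator seeded with
                      seed + replica index).
    n_beads_per_lipid : 1 (point lipid) or 3 (rigid rod, 0.3 nm bead spacing)
                      to exercise min-over-beads distance code.
    escape_offset   : nm beyond the capture radius at which an escaped lipid
                      is re-inserted, keeping re-entry diffusion-limited.
    """

    diffusion_coeff: dict[str, float]
    pocket_center: tuple[float, float] = (12.5, 12.5)
    capture_radius: float = 1.5
    escape_rate: dict[str, float] = field(default_factory=dict)
    box: tuple[float, float] = (25.0, 25.0)
    n_frames: int = 4000
    frame_interval: float = 1.0
    n_replicas: int = 3
    seed: int = 0
    n_beads_per_lipid: int = 1
    escape_offset: float = 0.1
    box_z: float = 10.0  # nominal membrane-normal box edge, nm

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.capture_radius < 0 or any(d < 0 for d in self.diffusion_coeff.values()):
            raise ValueError("radii and rates must be non-negative")
        if any(r < 0 for r in self.escape_rate.values()):
            raise ValueError("escape rates must be non-negative")
        if self.capture_radius >= min(self.box) / 2:
            raise ValueError("capture_radius must be smaller than half the box")
        if self.n_beads_per_lipid not in (1, 3):
            raise ValueError("n_beads_per_lipid must be 1 or 3")


def analytic_residence(params: KineticParams) -> dict[str, float]:
    """Ground-truth mean residence time (ns) per type: 1 / escape_rate."""
    out = {}
    for label, rate in params.escape_rate.items():
        if rate <= 0:
            raise ValueError(f"escape rate of {label} is 0: infinite residence time")
        out[label] = 1.0 / rate
    return out


def simulate_ensemble(
    params: KineticParams, composition: MembraneComposition
) -> TrajectoryEnsemble:
    """Generate a trapping-diffusion trajectory ensemble.

    Each lipid performs an independent 2D Brownian walk (per-axis displacement
    variance 2·D·Δt) under periodic wrapping.  On entering the capture disk it
    is trapped: its centre is jittered uniformly inside half the capture
    radius, and each frame it escapes with probability 1 − exp(−rate·Δt), upon
    which it is re-inserted ``escape_offset`` nm outside the disk in a uniform
    random direction.  Identical parameters and seed give identical output.
    """
    labels = [t for t in composition.counts if composition.counts[t] > 0]
    if not labels:
        raise ValueError("composition has no lipids")
    for t in labels:
        if t not in params.diffusion_coeff:
            raise ValueError(f"no diffusion coefficient for type {t}")

    type_per_lipid: list[str] = []
    for t in composition.counts:  # declaration order, deterministic
        type_per_lipid.extend([t] * composition.counts[t])
    n_lip = len(type_per_lipid)
    d_arr = np.array([params.diffusion_coeff[t] for t in type_per_lipid])
    rate_arr = np.array([params.escape_rate.get(t, 0.0) for t in type_per_lipid])
    p_escape = 1.0 - np.exp(-rate_arr * params.frame_interval)
    sigma = np.sqrt(2.0 * d_arr * params.frame_interval)  # per-axis step std

    box = np.asarray(params.box, dtype=float)
    center = np.asarray(params.pocket_center, dtype=float)
    nb = params.n_beads_per_lipid
    dt = params.frame_interval

    replicas: list[Replica] = []
    for rep in range(params.n_replicas):
        rng = np.random.default_rng(params.seed + rep)
        pos = rng.uniform(0.0, box, size=(n_lip, 2))
        # fixed per-lipid bead geometry (rigid rod along a random direction)
        if nb == 3:
            theta = rng.uniform(0, 2 * np.pi, size=n_lip)
            rod = 0.3 * np.stack([np.cos(theta), np.sin(theta)], axis=1)  # nm
        trapped = np.zeros(n_lip, dtype=bool)
        frames = np.empty((params.n_frames, n_lip * nb, 3))
        for f in range(params.n_frames):
            if f > 0:
                free = ~trapped
                step = rng.normal(0.0, 1.0, size=(n_lip, 2)) * sigma[:, None]
                pos[free] = (pos[free] + step[free]) % box
                if trapped.any():
                    # jitter inside the pocket, then draw escapes
                    n_tr = int(trapped.sum())
                    ang = rng.uniform(0, 2 * np.pi, size=n_tr)
                    rad = params.capture_radius * 0.5 * np.sqrt(
                        rng.uniform(0, 1, size=n_tr)
                    )
                    pos[trapped] = (
                        center + rad[:, None] * np.stack([np.cos(ang), np.sin(ang)], axis=1)
                    ) % box
                    esc = rng.uniform(0, 1, size=n_tr) < p_escape[trapped]
                    if esc.any():
                        idx = np.flatnonzero(trapped)[esc]
                        ang_e = rng.uniform(0, 2 * np.pi, size=len(idx))
                        r_out = params.capture_radius + params.escape_offset
                        pos[idx] = (
                            center
                            + r_out * np.stack([np.cos(ang_e), np.sin(ang_e)], axis=1)
                        ) % box
                        trapped[idx] = False
            if params.capture_radius > 0:
                delta = pos - center
                delta -= box * np.round(delta / box)
                dist = np.hypot(delta[:, 0], delta[:, 1])
                trapped |= dist <= params.capture_radius
            if nb == 1:
                frames[f, :, :2] = pos
                frames[f, :, 2] = 0.0
            else:
                beads = pos[:, None, :] + rod[:, None, :] * np.array([-1.0, 0.0, 1.0])[
                    None, :, None
                ]
                frames[f, :, :2] = (beads % box).reshape(n_lip * nb, 2)
                frames[f, :, 2] = 0.0
        replicas.append(
            Replica(
                times=np.arange(params.n_frames) * dt,
                boxes=np.tile(np.array([box[0], box[1], params.box_z]), (params.n_frames, 1)),
                positions=frames,
            )
        )

    lipids = [
        LipidMolecule(i, type_per_lipid[i], tuple(range(i * nb, (i + 1) * nb)))
        for i in range(n_lip)
    ]
    return TrajectoryEnsemble(
        replicas=replicas,
        frame_interval=dt,
        lipids=lipids,
        lipid_types=list(composition.counts),
    )
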