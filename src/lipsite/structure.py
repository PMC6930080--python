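"""Model- and trajectory-derived structural metrics.

Covers the quantities used to characterize the ATP synthase dimer and its
lipid complement: Shrake-Rupley solvent-accessible surface area with a
deterministic Fibonacci sphere lattice, buried interface area between two
selections, a census of modelled lipid residues, the angle between the two
monomer axes of a dimer, radial distribution functions and cavity-lipid
minimum distances under periodic boundaries.

Atom selections use a small text syntax, e.g.::

    chain A B and not resname HOH
    (resname CDL or resname PA) and chain M
    resid 10-45 and name CA

with clauses ``chain``, ``resname``, ``resid`` (single ids or ``lo-hi``
ranges), ``name``, ``all``, combined by ``and``/``or``/``not`` and
parentheses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import AtomRecord, StructureModel, TrajectoryEnsemble
from .kinetics import minimum_image

__all__ = [
    "Selection",
    "SasaResult",
    "RdfCurve",
    "DEFAULT_LIPID_NAMES",
    "CARDIOLIPIN_NAMES",
    "fibonacci_sphere",
    "shrake_rupley_sasa",
    "buried_surface_area",
    "lipid_census",
    "dimer_angle",
    "radial_distribution",
    "pair_min_distance",
]

#: Residue names counted as lipids by default.  CDL/CL are cardiolipin; the
#: remainder are common phospholipid codes (cryo-EM depositions often build
#: non-cardiolipin phospholipid as phosphatidic acid, code PA).  Water and
#: detergent codes (HOH, LMT, ...) are deliberately absent.
CARDIOLIPIN_NAMES = frozenset({"CDL", "CL", "CDN"})
DEFAULT_LIPID_NAMES = frozenset(
    {"CDL", "CL", "CDN", "PA", "LPP", "PC", "PE", "PG", "PS", "PI",
     "POP", "POV", "PEE", "PGV", "LHG", "CDL1", "3PE", "PTY"}
)


# ---------------------------------------------------------------------------
# selections


class Selection:
    """Deterministic, side-effect-free predicate over :class:`AtomRecord`."""

    def __init__(self, predicate: Callable[[AtomRecord], bool], label: str = "<sel>"):
        self._predicate = predicate
        self.label = label

    def __call__(self, atom: AtomRecord) -> bool:
        return bool(self._predicate(atom))

    def indices(self, model: StructureModel) -> np.ndarray:
        """Indices into ``model.atoms`` of the atoms matching this selection."""
        return np.array(
            [i for i, a in enumerate(model.atoms) if self(a)], dtype=int
        )

    def __and__(self, other: "Selection") -> "Selection":
        return Selection(lambda a: self(a) and other(a), f"({self.label} and {other.label})")

    def __or__(self, other: "Selection") -> "Selection":
        return Selection(lambda a: self(a) or other(a), f"({self.label} or {other.label})")

    def __invert__(self) -> "Selection":
        return Selection(lambda a: not self(a), f"(not {self.label})")

    def __repr__(self) -> str:
        return f"Selection({self.label})"

    # -- constructors -------------------------------------------------------

    @staticmethod
    def all() -> "Selection":
        return Selection(lambda a: True, "all")

    @staticmethod
    def chain(*ids: str) -> "Selection":
        ids_set = set(ids)
        return Selection(lambda a: a.chain_id in ids_set, f"chain {' '.join(ids)}")

    @staticmethod
    def resname(*names: str) -> "Selection":
        names_set = {n.upper() for n in names}
        return Selection(
            lambda a: a.residue_name.upper() in names_set, f"resname {' '.join(names)}"
        )

    @staticmethod
    def resid(*specs: str | int) -> "Selection":
        singles: set[int] = set()
        ranges: list[tuple[int, int]] = []
        for s in specs:
            s = str(s)
            if re.fullmatch(r"-?\d+", s):
                singles.add(int(s))
            elif re.fullmatch(r"(\d+)-(\d+)", s):
                lo, hi = s.split("-", 1)
                ranges.append((int(lo), int(hi)))
            else:
                raise ValueError(f"bad resid spec {s!r} (use N or LO-HI)")

        def pred(a: AtomRecord) -> bool:
            if a.residue_seq in singles:
                return True
            return any(lo <= a.residue_seq <= hi for lo, hi in ranges)

        return Selection(pred, f"resid {' '.join(map(str, specs))}")

    @staticmethod
    def name(*names: str) -> "Selection":
        names_set = {n.upper() for n in names}
        return Selection(
            lambda a: a.atom_name.upper() in names_set, f"name {' '.join(names)}"
        )

    # -- text syntax --------------------------------------------------------

    @staticmethod
    def parse(text: str) -> "Selection":
        """Parse the documented selection mini-language."""
        tokens = re.findall(r"\(|\)|[^\s()]+", text)
        pos = 0

        def peek() -> str | None:
            return tokens[pos] if pos < len(tokens) else None

        def advance() -> str:
            nonlocal pos
            tok = tokens[pos]
            pos += 1
            return tok

        KEYWORDS = {"chain", "resname", "resid", "name", "all", "and", "or", "not", "(", ")"}

        def parse_clause() -> Selection:
            kw = advance()
            if kw == "all":
                return Selection.all()
            args: list[str] = []
            while peek() is not None and peek() not in KEYWORDS:
                args.append(advance())
            if not args:
                raise ValueError(f"selection clause {kw!r} needs arguments")
            if kw == "chain":
                return Selection.chain(*args)
            if kw == "resname":
                return Selection.resname(*args)
            if kw == "resid":
                return Selection.resid(*args)
            if kw == "name":
                return Selection.name(*args)
            raise ValueError(f"unknown selection keyword {kw!r}")

        def parse_factor() -> Selection:
            tok = peek()
            if tok == "not":
                advance()
                return ~parse_factor()
            if tok == "(":
                advance()
                sel = parse_expr()
                if peek() != ")":
                    raise ValueError("unbalanced parenthesis in selection")
                advance()
                return sel
            return parse_clause()

        def parse_term() -> Selection:
            sel = parse_factor()
            while peek() == "and":
                advance()
                sel = sel & parse_factor()
            return sel

        def parse_expr() -> Selection:
            sel = parse_term()
            while peek() == "or":
                advance()
                sel = sel | parse_term()
            return sel

        if not tokens:
            raise ValueError("empty selection text")
        sel = parse_expr()
        if pos != len(tokens):
            raise ValueError(f"trailing tokens in selection: {' '.join(tokens[pos:])}")
        sel.label = text
        return sel


# ---------------------------------------------------------------------------
# SASA


@dataclass
class SasaResult:
    """Per-atom and total solvent-accessible surface area (Å²)."""

    atom_indices: np.ndarray  # indices into the model's atom list
    per_atom: np.ndarray  # Å²
    probe_radius: float  # Å
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden-angle lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def shrake_rupley_sasa(
    model: StructureModel,
    sel: Selection | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Shrake-Rupley SASA of the selected atoms, ignoring everything outside.

    Each atom is surrounded by ``n_points`` lattice points on its expanded
    sphere (r_vdw + probe); a point is accessible if it lies outside every
    neighbouring expanded sphere, and the per-atom area is the accessible
    fraction times 4π(r_vdw + probe)².  The point set is a deterministic
    Fibonacci lattice, so results are exactly reproducible.
    """
    if n_points < 60:
        raise ValueError("n_points must be at least 60")
    idx = sel.indices(model) if sel is not None else np.arange(len(model.atoms))
    if idx.size == 0:
        return SasaResult(idx, np.zeros(0), probe, n_points)
    coords = model.positions[idx]
    radii = model.radii[idx]
    if np.any(radii <= 0):
        bad = idx[np.flatnonzero(radii <= 0)[0]]
        raise ValueError(f"atom {model.atoms[bad].atom_name} has no radius assigned")
    expanded = radii + probe
    unit = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_reach = 2 * expanded.max()
    per_atom = np.empty(idx.size)
    for i in range(idx.size):
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], expanded[i] + expanded.max())
            if j != i and np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]
        ]
        pts = coords[i] + expanded[i] * unit
        if neighbors:
            ncoords = coords[neighbors]
            nrad = expanded[np.asarray(neighbors)]
            d2 = ((pts[:, None, :] - ncoords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nrad**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return SasaResult(idx, per_atom, probe, n_points)


def buried_surface_area(
    model: StructureModel,
    selA: Selection,
    selB: Selection,
    probe: float = 1.4,
    n_points: int = 960,
    halved: bool = True,
) -> float:
    """Interface area buried between two disjoint selections (Å²).

    BSA = [SASA(A alone) + SASA(B alone) − SASA(A∪B)] / 2 by default (the
    per-side interface-area convention); ``halved=False`` returns the full
    ΔSASA for comparison with tools that report the unhalved value.
    """
    ia, ib = set(selA.indices(model).tolist()), set(selB.indices(model).tolist())
    if ia & ib:
        raise ValueError(f"selections overlap on {len(ia & ib)} atoms")
    if not ia or not ib:
        raise ValueError("both selections must be non-empty")
    sa = shrake_rupley_sasa(model, selA, probe, n_points).total
    sb = shrake_rupley_sasa(model, selB, probe, n_points).total
    sab = shrake_rupley_sasa(model, selA | selB, probe, n_points).total
    delta = sa + sb - sab
    return delta / 2.0 if halved else delta


# ---------------------------------------------------------------------------
# census and geometry


def lipid_census(
    model: StructureModel, lipid_names: frozenset[str] | set[str] = DEFAULT_LIPID_NAMES
) -> tuple[dict[str, int], int]:
    """Count modelled lipid residues by name among the het residues.

    Each distinct (residue_name, chain, seq) counts once regardless of
    altlocs.  Returns (per-name counts, total).
    """
    seen = set()
    counts: dict[str, int] = {}
    for name, chain, seq in model.het_residues:
        if name.upper() not in {n.upper() for n in lipid_names}:
            continue
        key = (name, chain, seq)
        if key in seen:
            continue
        seen.add(key)
        counts[name] = counts.get(name, 0) + 1
    return counts, sum(counts.values())


def _principal_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if len(s) >= 2 and s[0] > 0 and (s[0] - s[1]) / s[0] < 0.05:
        raise ValueError(
            "degenerate selection: top two principal values within 5%, axis ill-defined"
        )
    return vt[0], coords.mean(axis=0)


def dimer_angle(
    model: StructureModel,
    monomer1_axis_sel: Selection,
    monomer2_axis_sel: Selection,
) -> float:
    """Angle (degrees) between the principal axes of the two monomer selections.

    Each monomer's rotation axis is the first principal component of its
    selected coordinates (recommended: c-ring plus central stalk).  Axes are
    oriented away from the midpoint between the two selections (the membrane
    midpoint of a dimer), so 0° means parallel monomers and larger angles mean
    a more V-shaped dimer.
    """
    c1 = model.positions[monomer1_axis_sel.indices(model)]
    c2 = model.positions[monomer2_axis_sel.indices(model)]
    if len(c1) < 3 or len(c2) < 3:
        raise ValueError("each axis selection needs at least 3 atoms (>=10 recommended)")
    u1, cen1 = _principal_axis(c1)
    u2, cen2 = _principal_axis(c2)
    mid = 0.5 * (cen1 + cen2)
    if np.dot(u1, cen1 - mid) < 0:
        u1 = -u1
    if np.dot(u2, cen2 - mid) < 0:
        u2 = -u2
    cosang = np.clip(np.dot(u1, u2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# trajectory-derived metrics


@dataclass
class RdfCurve:
    """Radial distribution function g(r) with bin centres (nm) and raw counts."""

    bin_centers: np.ndarray
    g: np.ndarray
    counts: np.ndarray


def _resolve_beads(sel, positions: np.ndarray) -> np.ndarray:
    """A bead selection is an int index array; a float vector is a fixed point."""
    arr = np.asarray(sel)
    if arr.dtype.kind == "f" and arr.ndim == 1 and arr.size in (2, 3):
        p = np.zeros(3)
        p[: arr.size] = arr
        return p[None, :]
    return positions[np.asarray(sel, dtype=int)]


def radial_distribution(
    traj: TrajectoryEnsemble,
    ref_sel,
    target_sel,
    bin_width: float = 0.1,
    r_max: float = 5.0,
) -> RdfCurve:
    """Minimum-image RDF of target beads around reference beads (or a point).

    g(r) is the pair-distance histogram normalized by the ideal-gas
    expectation; the normalization uses 2D annuli when the system is planar
    (z extent below 1e-6 nm) and 3D shells otherwise, and averages over all
    frames of all replicas.  ``r_max`` must fit within half the smallest box
    edge.
    """
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    n_frames_total = 0
    expected = np.zeros_like(counts)
    for rep in traj.replicas:
        planar = np.ptp(rep.positions[..., 2]) < 1e-6
        for f in range(rep.n_frames):
            box = rep.boxes[f]
            if r_max > min(box[:2] if planar else box) / 2:
                raise ValueError("r_max exceeds half the smallest box dimension")
            refs = _resolve_beads(ref_sel, rep.positions[f])
            targets = _resolve_beads(target_sel, rep.positions[f])
            delta = targets[None, :, :] - refs[:, None, :]
            delta = minimum_image(delta, box)
            d = np.sqrt((delta**2).sum(axis=-1)).ravel()
            d = d[d > 1e-12]  # drop self pairs
            counts += np.histogram(d, bins=edges)[0]
            n_ref, n_tgt = len(refs), len(targets)
            if planar:
                area = box[0] * box[1]
                shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
                expected += n_ref * n_tgt / area * shell
            else:
                vol = box[0] * box[1] * box[2]
                shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
                expected += n_ref * n_tgt / vol * shell
            n_frames_total += 1
    if n_frames_total == 0:
        raise ValueError("trajectory has no frames")
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RdfCurve(bin_centers=centers, g=g, counts=counts)


def pair_min_distance(
    traj: TrajectoryEnsemble,
    ref_sel,
    target_groups: Sequence[Sequence[int]],
) -> list[np.ndarray]:
    """Per-frame minimum-image minimum distance from each target group to the reference.

    Returns one (n_frames, n_groups) array per replica.  With the cavity
    selection as reference and one group per lipid this is exactly the
    distance series consumed by the binding-state machine.
    """
    if len(target_groups) == 0:
        raise ValueError("no target groups")
    out = []
    for rep in traj.replicas:
        mat = np.empty((rep.n_frames, len(target_groups)))
        for f in range(rep.n_frames):
            refs = _resolve_beads(ref_sel, rep.positions[f])
            if refs.size == 0:
                raise ValueError(f"empty reference selection in frame {f}")
            for gi, grp in enumerate(target_groups):
                beads = rep.positions[f][np.asarray(grp, dtype=int)]
                if beads.size == 0:
                    raise ValueError(f"empty target group {gi}")
                delta = beads[:, None, :] - refs[None, :, :]
                delta = minimum_image(delta, rep.boxes[f])
                mat[f, gi] = np.sqrt((delta**2).sum(axis=-1)).min()
        out.append(mat)
    return out
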