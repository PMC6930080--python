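"""Readers and writers for structure models, coarse-grained trajectories and result tables.

Structures (PDB/mmCIF, coordinates in Å) are parsed with gemmi and flattened
into :class:`StructureModel`, a plain list of :class:`AtomRecord` with van der
Waals radii assigned from :data:`VDW_RADII`.  Trajectories are multi-frame GRO
or XYZ sequences (coordinates in nm) plus a lipid-topology table mapping bead
indices to lipid molecules; they load into :class:`TrajectoryEnsemble`.
Kinetics code works in nm throughout; unit conversion happens only here.
"""

from __future__ import annotations

import dataclasses
import io
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "VDW_RADII",
    "AtomRecord",
    "StructureModel",
    "Frame",
    "Replica",
    "LipidMolecule",
    "TrajectoryEnsemble",
    "read_structure",
    "read_trajectory",
    "read_lipid_topology",
    "write_lipid_topology",
    "write_table",
    "read_table",
]

#: Bondi van der Waals radii in Å, used for SASA.  Hydrogens are listed for
#: completeness; deposited coarse/heavy-atom models usually omit them.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
    "FE": 2.05,
    "MN": 2.05,
    "CU": 1.40,
    "SE": 1.90,
}


@dataclass
class AtomRecord:
    """One atom of a coordinate model (Å)."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray  # shape (3,), Å
    vdw_radius: float  # Å

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AtomRecord):
            return NotImplemented
        return (
            self.serial == other.serial
            and self.atom_name == other.atom_name
            and self.element == other.element
            and self.residue_name == other.residue_name
            and self.residue_seq == other.residue_seq
            and self.chain_id == other.chain_id
            and np.allclose(self.position, other.position, atol=1e-3)
            and abs(self.vdw_radius - other.vdw_radius) < 1e-9
        )


@dataclass
class StructureModel:
    """Flattened coordinate model: atoms plus chain/entity bookkeeping.

    ``entities`` maps each polymer chain id to an entity label; chains with
    identical polymer sequences share a label.  ``het_residues`` lists the
    distinct non-polymer residues as ``(residue_name, chain_id, residue_seq)``.
    """

    atoms: list[AtomRecord] = field(default_factory=list)
    entities: dict[str, str] = field(default_factory=dict)
    het_residues: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) array of coordinates in Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.asarray([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.asarray([a.vdw_radius for a in self.atoms], dtype=float)

    def n_entities(self) -> int:
        """Number of distinct polymer entities (distinct protein sequences)."""
        return len(set(self.entities.values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureModel):
            return NotImplemented
        return (
            self.atoms == other.atoms
            and self.entities == other.entities
            and sorted(self.het_residues) == sorted(other.het_residues)
        )


@dataclass
class Frame:
    """One trajectory frame: time (ns), orthorhombic box (nm), bead positions (nm)."""

    time: float
    box: np.ndarray  # shape (3,), nm
    positions: np.ndarray  # shape (n_beads, 3), nm


@dataclass
class Replica:
    """One contiguous trajectory: stacked frames of a single simulation run."""

    times: np.ndarray  # (n_frames,), ns
    boxes: np.ndarray  # (n_frames, 3), nm
    positions: np.ndarray  # (n_frames, n_beads, 3), nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing within a replica")
        if np.any(self.boxes <= 0):
            raise ValueError("box components must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite bead position in trajectory")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(time=self.times[i], box=self.boxes[i], positions=self.positions[i])


@dataclass(frozen=True)
class LipidMolecule:
    """One lipid: an id, a type label (e.g. CDL, POPC) and its bead indices."""

    lipid_id: int
    type_label: str
    bead_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bead_indices) == 0:
            raise ValueError(f"lipid {self.lipid_id} has no beads")


@dataclass
class TrajectoryEnsemble:
    """A set of replica trajectories sharing one lipid topology."""

    replicas: list[Replica]
    frame_interval: float  # ns
    lipids: list[LipidMolecule]
    lipid_types: list[str]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for lip in self.lipids:
            if seen.intersection(lip.bead_indices):
                raise ValueError(f"lipid {lip.lipid_id}: bead indices overlap another lipid")
            seen.update(lip.bead_indices)
        for lab in {l.type_label for l in self.lipids}:
            if lab not in self.lipid_types:
                raise ValueError(f"lipid type {lab!r} missing from lipid_types")

    @property
    def n_lipids(self) -> int:
        return len(self.lipids)

    def types_of_lipids(self) -> np.ndarray:
        """Per-lipid type label, aligned with ``lipids`` order."""
        return np.asarray([l.type_label for l in self.lipids])


# ---------------------------------------------------------------------------
# structure reading


def _infer_element(atom_name: str, residue_name: str) -> str:
    """Infer an element symbol from a PDB-style atom name."""
    name = atom_name.strip()
    letters = re.sub(r"[^A-Za-z]", "", name).upper()
    if not letters:
        raise ValueError(f"cannot infer element for atom {atom_name!r} in {residue_name}")
    if letters[:2] in VDW_RADII and len(name) == 4 and name[0].isalpha():
        # 4-char names starting in column 13 may carry 2-letter elements (e.g. FE1)
        return letters[:2]
    if letters[0] in VDW_RADII:
        return letters[0]
    if letters[:2] in VDW_RADII:
        return letters[:2]
    raise ValueError(f"cannot infer element for atom {atom_name!r} in {residue_name}")


def read_structure(path: str | os.PathLike, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF coordinate file into a :class:`StructureModel`.

    Alternate locations are resolved by keeping the highest-occupancy copy of
    each atom (first occurrence wins ties).  Elements missing from the file
    are inferred from atom names; van der Waals radii come from
    :data:`VDW_RADII` and an unknown element is an error naming the atom.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "auto":
        ext = path.suffix.lower()
        if ext in {".pdb", ".ent"}:
            fmt = "pdb"
        elif ext in {".cif", ".mmcif"}:
            fmt = "mmcif"
        else:
            raise ValueError(f"cannot detect format from extension {ext!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc

    st.setup_entities()
    model = st[0]

    atoms: list[AtomRecord] = []
    het: list[tuple[str, str, int]] = []
    chain_seqs: dict[str, str] = {}
    for chain in model:
        polymer_seq: list[str] = []
        for res in chain:
            is_het = res.het_flag == "H"
            info = gemmi.find_tabulated_residue(res.name)
            is_water = info is not None and info.is_water()
            is_amino = info is not None and info.is_amino_acid()
            if not is_het and is_amino:
                polymer_seq.append(res.name)
            if is_het and not is_water:
                key = (res.name, chain.name, res.seqid.num)
                if key not in het:
                    het.append(key)
            # altloc resolution: best occupancy per atom name, first wins ties
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                prev = best.get(at.name)
                if prev is None:
                    best[at.name] = at
                    order.append(at.name)
                elif at.occ > prev.occ + 1e-9:
                    best[at.name] = at
            for name in order:
                at = best[name]
                el = "H" if at.element.is_hydrogen else at.element.name.upper()
                if el in {"", "X"}:
                    el = _infer_element(at.name, res.name)
                if el not in VDW_RADII:
                    try:
                        el = _infer_element(at.name, res.name)
                    except ValueError:
                        pass
                if el not in VDW_RADII:
                    raise ValueError(
                        f"unknown element {el!r} for atom {at.name} "
                        f"{res.name} {chain.name}{res.seqid.num}"
                    )
                atoms.append(
                    AtomRecord(
                        serial=at.serial,
                        atom_name=at.name,
                        element=el,
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        chain_id=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        vdw_radius=VDW_RADII[el],
                    )
                )
        if polymer_seq:
            chain_seqs[chain.name] = ",".join(polymer_seq)

    entities: dict[str, str] = {}
    seq_to_label: dict[str, str] = {}
    for chain_id, seq in chain_seqs.items():
        if seq not in seq_to_label:
            seq_to_label[seq] = f"E{len(seq_to_label) + 1}"
        entities[chain_id] = seq_to_label[seq]

    return StructureModel(atoms=atoms, entities=entities, het_residues=het)


# ---------------------------------------------------------------------------
# trajectory reading/writing


def _parse_gro_frames(path: Path) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        try:
            natoms = int(lines[i + 1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}: bad atom-count line at line {i + 2}") from exc
        m = re.search(r"t=\s*([-\d.eE+]+)", title)
        time = float(m.group(1)) if m else float(len(frames))
        pos = np.empty((natoms, 3))
        for k in range(natoms):
            line = lines[i + 2 + k]
            try:
                pos[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: unparseable GRO atom line {i + 3 + k}") from exc
        box_fields = lines[i + 2 + natoms].split()
        box = np.array([float(x) for x in box_fields[:3]])
        frames.append(Frame(time=time, box=box, positions=pos))
        i += natoms + 3
    return frames


def _parse_xyz_frames(path: Path) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: expected atom count at line {i + 1}") from exc
        comment = lines[i + 1]
        tm = re.search(r"time=\s*([-\d.eE+]+)", comment)
        time = float(tm.group(1)) if tm else float(len(frames))
        bm = re.search(r"box=\s*([-\d.eE+]+)\s+([-\d.eE+]+)\s+([-\d.eE+]+)", comment)
        box = (
            np.array([float(bm.group(1)), float(bm.group(2)), float(bm.group(3))])
            if bm
            else np.array([np.inf, np.inf, np.inf])
        )
        pos = np.empty((natoms, 3))
        for k in range(natoms):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise ValueError(f"{path}: unparseable XYZ atom line {i + 3 + k}")
            pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(Frame(time=time, box=box, positions=pos))
        i += natoms + 2
    return frames


def read_lipid_topology(path: str | os.PathLike) -> list[LipidMolecule]:
    """Read a lipid-topology TSV (columns lipid_id, type_label, bead_indices)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"type_label": str})
    lipids = []
    for row in df.itertuples(index=False):
        beads = tuple(int(x) for x in str(row.bead_indices).split(","))
        lipids.append(LipidMolecule(int(row.lipid_id), row.type_label, beads))
    return lipids


def write_lipid_topology(lipids: Sequence[LipidMolecule], path: str | os.PathLike) -> None:
    rows = [
        {
            "lipid_id": l.lipid_id,
            "type_label": l.type_label,
            "bead_indices": ",".join(str(b) for b in l.bead_indices),
        }
        for l in lipids
    ]
    write_table(rows, path)


def read_trajectory(
    paths: Sequence[str | os.PathLike],
    topology: Sequence[LipidMolecule] | str | os.PathLike | pd.DataFrame,
    lipid_types: Sequence[str] | None = None,
    format: str = "auto",
) -> TrajectoryEnsemble:
    """Read one or more frame-sequence files (one replica each) into an ensemble.

    ``topology`` may be a list of :class:`LipidMolecule`, a topology-TSV path,
    or an equivalent DataFrame.  Every frame must contain at least as many
    beads as the topology addresses; a mismatch is reported with the frame
    index.  The frame interval is inferred from the first two frame times.
    """
    if isinstance(topology, (str, os.PathLike)):
        lipids = read_lipid_topology(topology)
    elif isinstance(topology, pd.DataFrame):
        lipids = [
            LipidMolecule(
                int(r.lipid_id),
                str(r.type_label),
                tuple(int(x) for x in str(r.bead_indices).split(",")),
            )
            for r in topology.itertuples(index=False)
        ]
    else:
        lipids = list(topology)
    max_bead = max(b for l in lipids for b in l.bead_indices)

    replicas: list[Replica] = []
    interval = None
    for path in paths:
        path = Path(path)
        fmt = format
        if fmt == "auto":
            fmt = {".gro": "gro", ".xyz": "xyz"}.get(path.suffix.lower(), "")
            if not fmt:
                raise ValueError(f"cannot detect trajectory format of {path}")
        frames = _parse_gro_frames(path) if fmt == "gro" else _parse_xyz_frames(path)
        if not frames:
            raise ValueError(f"{path}: no frames")
        for fi, fr in enumerate(frames):
            if fr.positions.shape[0] <= max_bead:
                raise ValueError(
                    f"{path}: frame {fi} has {fr.positions.shape[0]} beads but the "
                    f"topology addresses bead index {max_bead}"
                )
        replicas.append(
            Replica(
                times=np.array([f.time for f in frames]),
                boxes=np.array([f.box for f in frames]),
                positions=np.stack([f.positions for f in frames]),
            )
        )
        if interval is None and len(frames) > 1:
            interval = frames[1].time - frames[0].time
    if interval is None:
        interval = 1.0
    if lipid_types is None:
        seen: list[str] = []
        for l in lipids:
            if l.type_label not in seen:
                seen.append(l.type_label)
        lipid_types = seen
    return TrajectoryEnsemble(
        replicas=replicas,
        frame_interval=float(interval),
        lipids=lipids,
        lipid_types=list(lipid_types),
    )


def write_gro(ensemble_replica: Replica, names: Sequence[str], path: str | os.PathLike) -> None:
    """Write one replica as a multi-frame GRO file (nm)."""
    with open(path, "w") as fh:
        for fi in range(ensemble_replica.n_frames):
            fr = ensemble_replica.frame(fi)
            fh.write(f"frame t= {fr.time:.6f}\n{len(fr.positions)}\n")
            for bi, p in enumerate(fr.positions):
                resid = (bi % 99999) + 1
                name = names[bi][:5]
                fh.write(
                    f"{resid:5d}{name:<5s}{name[:5]:>5s}{(bi % 99999) + 1:5d}"
                    f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}\n"
                )
            fh.write(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}\n")


def write_xyz(ensemble_replica: Replica, names: Sequence[str], path: str | os.PathLike) -> None:
    """Write one replica as a multi-frame XYZ file (nm, box on the comment line)."""
    with open(path, "w") as fh:
        for fi in range(ensemble_replica.n_frames):
            fr = ensemble_replica.frame(fi)
            fh.write(f"{len(fr.positions)}\n")
            fh.write(
                f"time= {fr.time:.6f} box= {fr.box[0]:.6f} {fr.box[1]:.6f} {fr.box[2]:.6f}\n"
            )
            for bi, p in enumerate(fr.positions):
                fh.write(
                    f"{names[bi]} {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n"
                )


# ---------------------------------------------------------------------------
# tables


def _rows_to_frame(rows: Iterable) -> pd.DataFrame:
    rows = list(rows)
    if rows and dataclasses.is_dataclass(rows[0]):
        rows = [dataclasses.asdict(r) for r in rows]
    return pd.DataFrame(rows)


def write_table(
    rows,
    path: str | os.PathLike,
    header_comments: Sequence[str] = (),
    columns: Sequence[str] | None = None,
) -> None:
    """Write records as a TSV with a header line and full-precision numbers.

    ``rows`` may be a DataFrame, a list of dicts, or a list of dataclass
    instances sharing a schema.  Serialization is deterministic: two calls
    with equal rows produce byte-identical files.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = _rows_to_frame(rows)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    elif df.empty and not len(df.columns):
        raise ValueError("cannot write an empty table without a schema (pass columns=)")
    buf = io.StringIO()
    for line in header_comments:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (``#`` comments ignored)."""
    return pd.read_csv(path, sep="\t", comment="#")
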