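"""Shared fixtures: crafted structure files and small synthetic ensembles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from lipsite import KineticParams, allocate_composition, simulate_ensemble

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

PDB_MINI = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
HETATM    3  P1  CDL A 101       5.000   5.000   5.000  1.00  0.00           P
END
"""

CIF_MINI = """\
data_mini
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 N N . ALA A 1 1 ? 11.104 6.134 -6.504 1.00 0.00 1 A 1
ATOM 2 C CA . ALA A 1 1 ? 11.639 6.071 -5.147 1.00 0.00 1 A 1
HETATM 3 P P1 . CDL B 2 . ? 5.000 5.000 5.000 1.00 0.00 101 A 1
"""

# two distinct protein chains (entities E1, E2), 3 cardiolipins + 2 phosphatidic
# acids in chain L, plus one water that the census must ignore
PDB_CENSUS = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.400   0.000   0.000  1.00  0.00           C
ATOM      3  N   GLY B   1      10.000   0.000   0.000  1.00  0.00           N
ATOM      4  CA  GLY B   1      11.400   0.000   0.000  1.00  0.00           C
HETATM    5  P1  CDL L 101      20.000   0.000   0.000  1.00  0.00           P
HETATM    6  P2  CDL L 101      21.000   0.000   0.000  1.00  0.00           P
HETATM    7  P1  CDL L 102      25.000   0.000   0.000  1.00  0.00           P
HETATM    8  P1  CDL L 103      30.000   0.000   0.000  1.00  0.00           P
HETATM    9  P1  PA  L 201      35.000   0.000   0.000  1.00  0.00           P
HETATM   10  P1  PA  L 202      40.000   0.000   0.000  1.00  0.00           P
HETATM   11  O   HOH W 301      45.000   0.000   0.000  1.00  0.00           O
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1      11.000   6.000  -5.000  0.40  0.00           C
ATOM      2  CA BALA A   1      11.500   6.000  -5.000  0.60  0.00           C
ATOM      3  CB AALA A   1      12.000   6.000  -5.000  0.50  0.00           C
ATOM      4  CB BALA A   1      12.500   6.000  -5.000  0.50  0.00           C
END
"""


@pytest.fixture
def pdb_mini(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(PDB_MINI)
    return p


@pytest.fixture
def cif_mini(tmp_path):
    p = tmp_path / "mini.cif"
    p.write_text(CIF_MINI)
    return p


@pytest.fixture
def pdb_census(tmp_path):
    p = tmp_path / "census.pdb"
    p.write_text(PDB_CENSUS)
    return p


@pytest.fixture
def pdb_altloc(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(PDB_ALTLOC)
    return p


def make_trapping_ensemble(
    n_lipids=200,
    fractions=None,
    escape=None,
    diffusion=0.05,
    n_frames=1000,
    n_replicas=1,
    seed=0,
    box=(20.0, 20.0),
    capture=1.5,
    n_beads=1,
):
    """Small trapping-diffusion ensemble used across kinetics tests."""
    fractions = fractions or {"CDL": 0.5, "POPC": 0.5}
    escape = escape or {"CDL": 0.01, "POPC": 0.025}
    comp = allocate_composition(n_lipids, fractions)
    params = KineticParams(
        diffusion_coeff={t: diffusion for t in fractions},
        pocket_center=(box[0] / 2, box[1] / 2),
        capture_radius=capture,
        escape_rate=escape,
        box=box,
        n_frames=n_frames,
        frame_interval=1.0,
        n_replicas=n_replicas,
        seed=seed,
        n_beads_per_lipid=n_beads,
    )
    return params, comp, simulate_ensemble(params, comp)


# --- independent oracles (kept deliberately naive) -------------------------


def brute_force_hysteresis(distances, r_on, r_off):
    """Frame-by-frame hysteresis labeller, written independently of the package."""
    states = []
    inside = False
    for d in distances:
        if inside:
            inside = d <= r_off
        else:
            inside = d <= r_on
        states.append(1 if inside else 0)
    return states


def brute_force_pair_counts(state_rows, lag_frames):
    """Double loop over (lipid, frame) counting ordered state pairs."""
    counts = {"oi": 0, "ii": 0, "io": 0, "oo": 0}
    for row in state_rows:
        for k in range(len(row) - lag_frames):
            a, b = row[k], row[k + lag_frames]
            key = ("o" if a == 0 else "i") + ("o" if b == 0 else "i")
            counts[key] += 1
    return counts


def exact_mw_pvalue(x, y):
    """Two-sided Mann-Whitney p by full enumeration of label assignments."""
    import itertools

    x, y = list(x), list(y)
    pooled = x + y
    nx = len(x)

    def u_of(sample_idx):
        xs = [pooled[i] for i in sample_idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(sample_idx)]
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_of(tuple(range(nx)))
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), nx)]
    n = len(us)
    lo = sum(1 for u in us if u <= u_obs) / n
    hi = sum(1 for u in us if u >= u_obs) / n
    return min(1.0, 2 * min(lo, hi))
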