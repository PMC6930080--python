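"""SASA, buried interface area, census, dimer geometry, RDF and distances."""

import numpy as np
import pytest

from lipsite import (
    Selection,
    buried_surface_area,
    dimer_angle,
    lipid_census,
    pair_min_distance,
    radial_distribution,
    read_structure,
    shrake_rupley_sasa,
)
from lipsite.io_formats import (
    VDW_RADII,
    AtomRecord,
    LipidMolecule,
    Replica,
    StructureModel,
    TrajectoryEnsemble,
)


def atom(serial, pos, el="C", name="C", res="ALA", seq=1, chain="A"):
    return AtomRecord(
        serial, name, el, res, seq, chain, np.asarray(pos, dtype=float), VDW_RADII[el]
    )


def cluster_model(n, seed, spread=4.0):
    rng = np.random.default_rng(seed)
    return StructureModel(
        atoms=[atom(i, rng.uniform(0, spread, 3)) for i in range(n)]
    )


class TestSasa:
    def test_isolated_sphere_is_analytic(self):
        m = StructureModel(atoms=[atom(1, [0, 0, 0])])
        res = shrake_rupley_sasa(m)
        assert res.total == pytest.approx(4 * np.pi * 3.10**2, rel=0.01)
        assert res.per_atom.sum() == pytest.approx(res.total)

    def test_distant_atoms_do_not_interact(self):
        m = StructureModel(atoms=[atom(1, [0, 0, 0]), atom(2, [100, 0, 0])])
        single = 4 * np.pi * 3.10**2
        assert shrake_rupley_sasa(m).total == pytest.approx(2 * single, rel=0.01)

    @pytest.mark.parametrize("d", [1.5, 3.0, 5.0])
    def test_two_sphere_overlap_matches_cap_formula(self, d):
        m = StructureModel(atoms=[atom(1, [0, 0, 0]), atom(2, [d, 0, 0])])
        R = 1.70 + 1.4
        exact = 2 * (4 * np.pi * R**2 - 2 * np.pi * R * (R - d / 2))
        assert shrake_rupley_sasa(m).total == pytest.approx(exact, rel=0.02)

    def test_lattice_converges(self):
        m = cluster_model(50, seed=7)
        a = shrake_rupley_sasa(m, n_points=960).total
        b = shrake_rupley_sasa(m, n_points=4000).total
        assert abs(a - b) / b < 0.01

    def test_agrees_with_independent_implementation(self):
        """Cross-check against Biopython's Shrake-Rupley on a random cluster."""
        from Bio.PDB.SASA import ShrakeRupley
        from Bio.PDB.StructureBuilder import StructureBuilder

        m = cluster_model(25, seed=3)
        sb = StructureBuilder()
        sb.init_structure("x")
        sb.init_model(0)
        sb.init_chain("A")
        sb.init_seg(" ")
        for i, a in enumerate(m.atoms):
            sb.init_residue("ALA", " ", i + 1, " ")
            sb.init_atom("CA", a.position, 0.0, 1.0, " ", "CA", i + 1, "C")
        struct = sb.get_structure()
        sr = ShrakeRupley(probe_radius=1.4, n_points=960, radii_dict={"C": 1.70})
        sr.compute(struct, level="S")
        ours = shrake_rupley_sasa(m, n_points=960).total
        assert ours == pytest.approx(struct.sasa, rel=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            shrake_rupley_sasa(cluster_model(2, 0), n_points=10)


class TestBuriedSurfaceArea:
    def _two_pairs(self, gap):
        atoms = [
            atom(1, [0, 0, 0], chain="A"),
            atom(2, [0, 3.5, 0], chain="A"),
            atom(3, [gap, 0, 0], chain="B"),
            atom(4, [gap, 3.5, 0], chain="B"),
        ]
        return StructureModel(atoms=atoms)

    def test_no_contact_means_zero(self):
        m = self._two_pairs(gap=20.0)
        bsa = buried_surface_area(m, Selection.chain("A"), Selection.chain("B"))
        assert bsa == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_in_arguments_and_sides(self):
        m = self._two_pairs(gap=4.0)
        ab = buried_surface_area(m, Selection.chain("A"), Selection.chain("B"))
        ba = buried_surface_area(m, Selection.chain("B"), Selection.chain("A"))
        assert ab == pytest.approx(ba)
        assert ab > 0
        # symmetric dimer: per-side burial equals half the total SASA loss
        full = buried_surface_area(
            m, Selection.chain("A"), Selection.chain("B"), halved=False
        )
        assert full == pytest.approx(2 * ab)

    def test_matches_high_resolution_oracle(self):
        m = self._two_pairs(gap=4.5)
        fast = buried_surface_area(m, Selection.chain("A"), Selection.chain("B"))
        fine = buried_surface_area(
            m, Selection.chain("A"), Selection.chain("B"), n_points=10000
        )
        assert fast == pytest.approx(fine, rel=0.02, abs=0.5)

    def test_overlapping_selections_rejected(self):
        m = self._two_pairs(gap=4.0)
        with pytest.raises(ValueError, match="overlap"):
            buried_surface_area(m, Selection.chain("A"), Selection.all())


class TestLipidCensus:
    def test_census_fixture(self, pdb_census):
        model = read_structure(pdb_census)
        counts, total = lipid_census(model)
        assert counts == {"CDL": 3, "PA": 2}
        assert total == 5

    def test_water_and_unlisted_names_excluded(self, pdb_census):
        model = read_structure(pdb_census)
        counts, total = lipid_census(model, lipid_names={"CDL"})
        assert counts == {"CDL": 3} and total == 3

    def test_empty_model_empty_census(self):
        counts, total = lipid_census(StructureModel())
        assert counts == {} and total == 0

    def test_duplicate_residue_counted_once(self):
        m = StructureModel(
            het_residues=[("CDL", "L", 1), ("CDL", "L", 1), ("CDL", "L", 2)]
        )
        counts, total = lipid_census(m)
        assert counts == {"CDL": 2} and total == 2


class TestDimerAngle:
    def _rod_model(self, angle_deg, n=20, rotate=None, translate=None):
        half = np.deg2rad(angle_deg / 2)
        u1 = np.array([np.sin(half), 0, np.cos(half)])
        u2 = np.array([-np.sin(half), 0, np.cos(half)])
        pts = []
        for i in range(n):
            pts.append(((5 + i) * u1, "A"))
            pts.append(((5 + i) * u2, "B"))
        if rotate is not None:
            pts = [(rotate @ p, c) for p, c in pts]
        if translate is not None:
            pts = [(p + translate, c) for p, c in pts]
        return StructureModel(
            atoms=[atom(i, p, chain=c) for i, (p, c) in enumerate(pts)]
        )

    def test_parallel_rods_are_zero_degrees(self):
        m = self._rod_model(0.0)
        # identical axes: shift chain B sideways so selections are distinct rods
        for a in m.atoms:
            if a.chain_id == "B":
                a.position = a.position + np.array([8.0, 0, 0])
        ang = dimer_angle(m, Selection.chain("A"), Selection.chain("B"))
        assert ang == pytest.approx(0.0, abs=0.5)

    @pytest.mark.parametrize("target", [45.0, 100.0])
    def test_constructed_angles_recovered(self, target):
        m = self._rod_model(target)
        ang = dimer_angle(m, Selection.chain("A"), Selection.chain("B"))
        assert ang == pytest.approx(target, abs=0.5)

    def test_invariant_under_rigid_motion(self):
        th = np.deg2rad(33.0)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        a = dimer_angle(
            self._rod_model(45.0), Selection.chain("A"), Selection.chain("B")
        )
        b = dimer_angle(
            self._rod_model(45.0, rotate=rot, translate=np.array([5.0, -3.0, 11.0])),
            Selection.chain("A"),
            Selection.chain("B"),
        )
        assert a == pytest.approx(b, abs=1e-6)

    def test_isotropic_selection_rejected(self):
        rng = np.random.default_rng(0)
        # near-spherical blob: top two principal values within 5%
        pts = rng.normal(0, 1, size=(500, 3))
        m = StructureModel(
            atoms=[atom(i, p, chain="A") for i, p in enumerate(pts)]
            + [atom(1000 + i, p + [20, 0, 0], chain="B") for i, p in enumerate(pts[:20] * [1, 1, 5])]
        )
        with pytest.raises(ValueError, match="degenerate"):
            dimer_angle(m, Selection.chain("A"), Selection.chain("B"))


class TestSelections:
    def test_parse_and_combinators_agree(self, pdb_census):
        model = read_structure(pdb_census)
        parsed = Selection.parse("(resname CDL or resname PA) and chain L")
        api = (Selection.resname("CDL") | Selection.resname("PA")) & Selection.chain("L")
        np.testing.assert_array_equal(parsed.indices(model), api.indices(model))
        assert len(parsed.indices(model)) == 6

    def test_not_and_resid_range(self, pdb_census):
        model = read_structure(pdb_census)
        sel = Selection.parse("resid 101-103 and not resname PA")
        names = {model.atoms[i].residue_name for i in sel.indices(model)}
        assert names == {"CDL"}

    def test_parse_errors(self):
        with pytest.raises(ValueError):
            Selection.parse("chain")
        with pytest.raises(ValueError):
            Selection.parse("(chain A")
        with pytest.raises(ValueError):
            Selection.parse("frobnicate X")


def planar_ensemble(positions, box=(20.0, 20.0, 10.0), dt=1.0):
    """positions: (F, N, 2) -> single-replica planar ensemble."""
    pos = np.zeros(positions.shape[:2] + (3,))
    pos[..., :2] = positions
    rep = Replica(
        times=np.arange(positions.shape[0], dtype=float),
        boxes=np.tile(box, (positions.shape[0], 1)),
        positions=pos,
    )
    lipids = [LipidMolecule(i, "X", (i,)) for i in range(positions.shape[1])]
    return TrajectoryEnsemble([rep], dt, lipids, ["X"])


class TestRdf:
    def test_uniform_system_is_flat(self):
        rng = np.random.default_rng(0)
        traj = planar_ensemble(rng.uniform(0, 20, size=(40, 500, 2)))
        curve = radial_distribution(
            traj, np.arange(500), np.arange(500), bin_width=0.25, r_max=5.0
        )
        sel = curve.bin_centers >= 1.0
        np.testing.assert_allclose(curve.g[sel], 1.0, atol=0.05)

    def test_fixed_distance_occupies_single_bin(self):
        pos = np.array([[[5.0, 5.0], [7.0, 5.0]]])  # one ref, one target at d=2
        traj = planar_ensemble(pos)
        curve = radial_distribution(
            traj, np.array([0]), np.array([1]), bin_width=0.5, r_max=5.0
        )
        occupied = np.flatnonzero(curve.counts)
        assert occupied.tolist() == [4]  # bin [2.0, 2.5)

    def test_uniform_counts_integrate_to_pair_count(self):
        rng = np.random.default_rng(1)
        n = 300
        traj = planar_ensemble(rng.uniform(0, 20, size=(10, n, 2)))
        r_max = 9.0
        curve = radial_distribution(
            traj, np.arange(n), np.arange(n), bin_width=0.1, r_max=r_max
        )
        # expected ordered pairs within r_max per frame: n*(n-1)*pi r^2 / A
        expected = 10 * n * (n - 1) * np.pi * r_max**2 / 400.0
        assert curve.counts.sum() == pytest.approx(expected, rel=0.05)

    def test_r_max_exceeding_half_box_rejected(self):
        traj = planar_ensemble(np.zeros((1, 2, 2)))
        with pytest.raises(ValueError, match="half"):
            radial_distribution(traj, np.array([0]), np.array([1]), r_max=11.0)


class TestPairMinDistance:
    def test_coincident_beads_give_zero(self):
        traj = planar_ensemble(np.array([[[3.0, 3.0], [3.0, 3.0]]]))
        d = pair_min_distance(traj, np.array([0]), [[1]])
        assert d[0][0, 0] == 0.0

    def test_minimum_image_wrap(self):
        traj = planar_ensemble(np.array([[[0.0, 0.0], [19.5, 0.0]]]))
        d = pair_min_distance(traj, np.array([0]), [[1]])
        assert d[0][0, 0] == pytest.approx(0.5)

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(2)
        traj = planar_ensemble(rng.uniform(0, 20, size=(5, 2, 2)))
        d1 = pair_min_distance(traj, np.array([0]), [[1]])
        d2 = pair_min_distance(traj, np.array([1]), [[0]])
        np.testing.assert_allclose(d1[0], d2[0])

    def test_matches_state_machine_input(self):
        """pair_min_distance equals the kinetics module's distance series."""
        from lipsite.kinetics import BindingSite, min_distance_series
        from conftest import make_trapping_ensemble

        _, _, traj = make_trapping_ensemble(n_lipids=15, n_frames=20, n_beads=3)
        site = BindingSite(center=np.array([10.0, 10.0]), r_on=1.8, r_off=3.5)
        via_kinetics = min_distance_series(traj, site)[0]
        via_structure = pair_min_distance(
            traj, np.array([10.0, 10.0]), [list(l.bead_indices) for l in traj.lipids]
        )[0]
        np.testing.assert_allclose(via_kinetics, via_structure.T)
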