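import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from qsar4d.align_grid import (
    AlignmentSpec,
    DegenerateAlignmentError,
    GridSpec,
    OccupancyMatrix,
    assign_ipe,
    cell_center_distance,
    compute_gcods,
    superpose_three_point,
)
from qsar4d.ensembles import Conformation, ConformerEnsemble

from conftest import single_conformer_ensemble

ALIGN = AlignmentSpec("alignment1", (0, 1, 2))


def random_structure(rng, n_atoms=5):
    return rng.normal(scale=3.0, size=(n_atoms, 3)) + 0.31  # off-lattice


class TestSuperposition:
    def test_identity_when_already_on_reference(self):
        rng = np.random.default_rng(0)
        coords = random_structure(rng)
        out = superpose_three_point(coords, coords, ALIGN)
        assert np.allclose(out, coords, atol=1e-10)

    def test_recovers_constructed_rigid_motion(self):
        rng = np.random.default_rng(1)
        ref = random_structure(rng)
        rot = Rotation.from_euler("z", 90, degrees=True)
        moved = rot.apply(ref) + np.array([1.0, 2.0, 3.0])
        out = superpose_three_point(moved, ref, ALIGN)
        # brute-force check: the full structure, not just the triple, returns
        assert np.allclose(out, ref, atol=1e-10)
        triple_rmsd = np.sqrt(((out[:3] - ref[:3]) ** 2).mean())
        assert triple_rmsd < 1e-10

    def test_no_reflection_allowed(self):
        rng = np.random.default_rng(2)
        ref = random_structure(rng)
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        out = superpose_three_point(mirrored, ref, ALIGN)
        # a reflection would fit the triple exactly; a proper rotation cannot
        v1, v2 = out[1] - out[0], out[2] - out[0]
        r1, r2 = ref[1] - ref[0], ref[2] - ref[0]
        assert np.dot(np.cross(v1, v2), np.cross(r1, r2)) > 0

    def test_collinear_triple_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [1, 1, 1]])
        with pytest.raises(DegenerateAlignmentError):
            superpose_three_point(line, line, ALIGN)

    def test_duplicate_indices_rejected(self):
        with pytest.raises(DegenerateAlignmentError):
            AlignmentSpec("bad", (0, 0, 1))


class TestIpeTyping:
    def test_protonated_amine_nitrogen(self):
        # R3NH+ fragment: charged nitrogen with one proton
        ens = single_conformer_ensemble(
            np.zeros((5, 3)), ["N", "H", "C", "C", "C"],
            bonds=[(0, 1), (0, 2), (0, 3), (0, 4)],
            formal_charges=np.array([1.0, 0, 0, 0, 0]),
        )
        classes = assign_ipe(ens)
        assert classes[0] == frozenset({"any", "p+", "hbd"})
        assert "p+" in classes[1]  # the ammonium proton polarizes positive

    def test_phenolic_hydroxyl_oxygen(self):
        # aromatic C-O-H: six aromatic carbons with hydrogens plus the hydroxyl
        elements = ["C"] * 6 + ["O", "H"] + ["H"] * 5
        bonds = [(i, (i + 1) % 6) for i in range(6)] + [(0, 6), (6, 7)] + [
            (i + 1, 8 + i) for i in range(5)
        ]
        ens = single_conformer_ensemble(np.zeros((13, 3)), elements, bonds)
        classes = assign_ipe(ens)
        assert classes[6] == frozenset({"any", "p-", "hba", "hbd"})

    def test_benzene_carbon(self):
        elements = ["C"] * 6 + ["H"] * 6
        bonds = [(i, (i + 1) % 6) for i in range(6)] + [(i, 6 + i) for i in range(6)]
        ens = single_conformer_ensemble(np.zeros((12, 3)), elements, bonds)
        classes = assign_ipe(ens)
        assert classes[0] == frozenset({"any", "ar", "np"})

    def test_saturated_ring_not_aromatic(self):
        # cyclohexane: ring carbons carry two hydrogens each
        elements = ["C"] * 6 + ["H"] * 12
        bonds = [(i, (i + 1) % 6) for i in range(6)]
        bonds += [(i, 6 + 2 * i) for i in range(6)] + [(i, 7 + 2 * i) for i in range(6)]
        ens = single_conformer_ensemble(np.zeros((18, 3)), elements, bonds)
        assert all("ar" not in c for c in assign_ipe(ens))

    def test_unknown_element_without_charges_rejected(self):
        ens = single_conformer_ensemble(np.zeros((1, 3)), ["Xx"])
        with pytest.raises(ValueError, match="Xx"):
            assign_ipe(ens)


class TestCellGeometry:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 13, 1), (-1, 8, 2), 5.48),
            ((0, 1, -2), (0, -2, -1), 3.16),
            ((0, 10, -2), (0, 12, -1), 2.24),
            ((0, 2, 2), (1, 3, 6), 4.24),
        ],
    )
    def test_unit_lattice_distances(self, a, b, expected):
        assert round(cell_center_distance(a, b, 1.0), 2) == expected

    def test_identical_cells(self):
        assert cell_center_distance((3, -1, 2), (3, -1, 2), 2.0) == 0.0

    def test_scales_with_cell_size(self):
        assert cell_center_distance((0, 0, 0), (1, 0, 0), 2.0) == 2.0


class TestOccupancy:
    def test_single_conformation_single_atom(self):
        ens = single_conformer_ensemble([[0.5, 0.5, 0.5]], ["C"], compound_id=1)
        occ = compute_gcods([ens])
        assert occ.values.at[1, (0, 0, 0, "np")] == 1.0
        assert occ.values.at[1, (0, 0, 0, "any")] == 1.0

    def test_partial_occupancy_fraction(self):
        # one atom sits in the origin cell for 500 of 2000 snapshots
        confs = [
            Conformation(np.array([[0.5, 0.5, 0.5]]), 0.0) for _ in range(500)
        ] + [Conformation(np.array([[5.5, 0.5, 0.5]]), 0.0) for _ in range(1500)]
        ens = ConformerEnsemble(1, confs, ["C"])
        occ = compute_gcods([ens], classes=("any",))
        assert occ.values.at[1, (0, 0, 0, "any")] == 0.25

    def test_occupancy_uncapped_for_multiple_atoms(self):
        ens = single_conformer_ensemble(
            [[0.2, 0.2, 0.2], [0.8, 0.8, 0.8]], ["C", "C"], compound_id=1
        )
        occ = compute_gcods([ens], classes=("any",))
        assert occ.values.at[1, (0, 0, 0, "any")] == 2.0

    def test_any_class_dominates_all_others(self):
        rng = np.random.default_rng(3)
        ens = single_conformer_ensemble(
            rng.uniform(0, 2, size=(6, 3)), ["C", "N", "O", "H", "H", "S"],
            bonds=[(0, 1), (1, 2), (2, 3), (0, 4), (0, 5)], compound_id=9,
        )
        occ = compute_gcods([ens])
        frame = occ.values
        for (x, y, z, ipe) in frame.columns:
            if ipe == "any":
                continue
            assert frame.at[9, (x, y, z, ipe)] <= frame.at[9, (x, y, z, "any")]

    def test_any_occupancy_sums_to_mean_atom_count(self):
        rng = np.random.default_rng(4)
        confs = [Conformation(rng.uniform(0, 4, (7, 3)), 0.0) for _ in range(20)]
        ens = ConformerEnsemble(2, confs, ["C"] * 7)
        occ = compute_gcods([ens], classes=("any",))
        assert occ.values.loc[2].sum() == pytest.approx(7.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        """A global rotation+translation of everything leaves occupancies unchanged."""
        rng = np.random.default_rng(5)
        ref = rng.normal(scale=2.0, size=(5, 3)) + 0.13
        ensembles = []
        for cid in (1, 2):
            confs = [
                Conformation(ref + rng.normal(scale=0.3, size=ref.shape), 0.0)
                for _ in range(10)
            ]
            ensembles.append(ConformerEnsemble(cid, confs, ["C"] * 5))
        occ = compute_gcods(ensembles, reference=ref, alignment=ALIGN, classes=("any",))

        rot = Rotation.from_euler("xyz", [31, -47, 102], degrees=True)
        shift = np.array([2.1, -0.7, 5.5])
        moved_ref = rot.apply(ref) + shift
        moved = [
            ConformerEnsemble(
                e.compound_id,
                [Conformation(rot.apply(c.coords) + shift, 0.0) for c in e.conformations],
                e.atom_elements,
            )
            for e in ensembles
        ]
        occ2 = compute_gcods(moved, reference=moved_ref, alignment=ALIGN, classes=("any",))
        assert occ.values.equals(occ2.values)

    def test_linearity_against_per_conformer_oracle(self):
        """Ensemble occupancy equals the average of single-snapshot occupancies."""
        rng = np.random.default_rng(6)
        confs = [Conformation(rng.uniform(0, 3, (4, 3)), 0.0) for _ in range(8)]
        ens = ConformerEnsemble(1, confs, ["C"] * 4)
        occ = compute_gcods([ens], classes=("any",))

        acc = {}
        for c in confs:
            single = ConformerEnsemble(1, [c], ["C"] * 4)
            m = compute_gcods([single], classes=("any",)).values
            for key in m.columns:
                acc[key] = acc.get(key, 0.0) + m.at[1, key] / len(confs)
        for key, v in acc.items():
            assert occ.values.at[1, key] == pytest.approx(v, abs=1e-12)

    def test_sparse_csv_round_trip(self, tmp_path):
        ens = single_conformer_ensemble(
            [[0.5, 0.5, 0.5], [1.5, 0.5, 0.5]], ["C", "C"], compound_id=3
        )
        occ = compute_gcods([ens], classes=("any",))
        path = tmp_path / "occ.csv"
        occ.to_sparse_csv(path)
        back = OccupancyMatrix.from_sparse_csv(path)
        assert back.values.loc[3].to_dict() == occ.values.loc[3].to_dict()

    def test_negative_occupancy_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            OccupancyMatrix(pd.DataFrame({"a": [-0.1]}, index=[1]))
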