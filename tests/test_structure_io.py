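"""Structure I/O: parsing, round trips, selection, symmetry, masses."""

import numpy as np
import pytest

from trimergeo import (SymmetryOperator, build_cyclic_assembly,
                       expand_crystal_symmetry, extract_sequence,
                       molecular_weight, read_structure, select,
                       write_structure)
from trimergeo.errors import (CapabilityError, ConfigurationError, ParseError,
                              SelectionError, ValidationError)
from trimergeo.model import build_model
from trimergeo.structure_io import (axis_angle_of_rotation,
                                    rotation_about_axis)


def _toy_model():
    m = build_model([
        ("ALA", 1, [("N", "N", [0.0, 0.5, 1.0]),
                    ("CA", "C", [1.25, 0.5, 1.0]),
                    ("CB", "C", [1.5, -0.5, 2.25])]),
        ("MSE", 2, [("CA", "C", [4.0, 0.0, 0.0]),
                    ("SE", "SE", [5.0, 1.0, 0.0])]),
        ("GLY", 4, [("CA", "C", [7.0, 0.25, -1.0])]),  # note the numbering gap
    ], id="toy")
    m.cell = (50.0, 50.0, 50.0, 90.0, 90.0, 90.0)
    m.space_group = "P 21 3"
    return m


class TestRoundTrips:
    def test_pdb_written_file_round_trips_byte_identically(self, tmp_path):
        m = _toy_model()
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_structure(m, p1)
        write_structure(read_structure(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_json_dump_round_trips_field_for_field(self, tmp_path):
        m = _toy_model()
        # arbitrary-precision coordinates survive the JSON path exactly
        m.chains[0].residues[0].atoms[0].position = np.array(
            [0.123456789012, -3.987654321, 2.0 / 3.0])
        path = tmp_path / "m.json"
        write_structure(m, path)
        assert read_structure(path) == m

    def test_pdb_read_applies_altloc_policy(self, tmp_path):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30 10.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70 10.00           C\n"
            "END\n")
        path = tmp_path / "alt.pdb"
        path.write_text(text)
        model = read_structure(path)
        atoms = model.atoms()
        assert len(atoms) == 1
        assert atoms[0].position[0] == pytest.approx(5.0)  # higher occupancy

    def test_missing_file_and_unknown_format(self, tmp_path):
        with pytest.raises(ParseError):
            read_structure(tmp_path / "nope.pdb")
        (tmp_path / "x.xyz").write_text("")
        with pytest.raises(ConfigurationError):
            read_structure(tmp_path / "x.xyz")


class TestSelect:
    def test_identity_selection(self, protomer):
        full = select(protomer, "A", [(1, 10_000)])
        assert full.n_atoms() == protomer.n_atoms()

    def test_gap_residues_silently_absent(self):
        m = _toy_model()
        sub = select(m, "A", [(1, 4)])
        assert [r.number for r in sub.chains[0].residues] == [1, 2, 4]
        assert select(m, "A", [(3, 3)]).n_atoms() == 0

    def test_malformed_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            select(_toy_model(), "A", [(5, 4)])

    def test_unknown_chain_rejected(self):
        with pytest.raises(SelectionError):
            select(_toy_model(), "Q", [(1, 2)])


class TestCyclicAssembly:
    def test_c3_closure_under_additional_rotation(self, protomer):
        axis_point = np.array([1.0, -2.0, 0.5])
        axis = np.array([0.3, 0.4, 1.0])
        asm = build_cyclic_assembly(protomer, axis_point, axis, 3)
        rot = rotation_about_axis(axis, 120.0)
        moved = asm.transformed(rot, axis_point - rot @ axis_point)
        # the rotated assembly is the same point set (chains permuted)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(asm.coords()).query(moved.coords())
        assert d.max() < 1e-9

    def test_c2_doubles_off_axis_distance(self):
        m = build_model([("GLY", 1, [("CA", "C", [3.0, 0.0, 7.0])])])
        asm = build_cyclic_assembly(m, np.zeros(3), np.array([0, 0, 1.0]), 2)
        a, b = asm.atoms()
        assert np.linalg.norm(a.position - b.position) == pytest.approx(6.0)

    def test_chain_relabelling_and_serials(self, protomer):
        asm = build_cyclic_assembly(protomer, np.zeros(3),
                                    np.array([0, 0, 1.0]), 3)
        assert asm.chain_ids == ["A", "B", "C"]
        serials = [a.serial for a in asm.iter_atoms()]
        assert len(serials) == len(set(serials))

    def test_invalid_order_rejected(self, protomer):
        with pytest.raises(ConfigurationError):
            build_cyclic_assembly(protomer, np.zeros(3),
                                  np.array([0, 0, 1.0]), 1)


class TestCrystalSymmetry:
    def test_identity_only_returns_model_unchanged(self, tmp_path):
        m = _toy_model()
        path = tmp_path / "t.pdb"
        write_structure(m, path)
        model = read_structure(path)
        assert len(model.symmetry_operators) == 12  # P 21 3
        identity = next(i for i, op in enumerate(model.symmetry_operators)
                        if op.is_identity)
        assert expand_crystal_symmetry(model, [identity]) == model

    def test_cubic_threefold_gives_equidistant_copies(self, tmp_path):
        m = _toy_model()
        path = tmp_path / "t.pdb"
        write_structure(m, path)
        model = read_structure(path)
        threefolds = [i for i, op in enumerate(model.symmetry_operators)
                      if abs(axis_angle_of_rotation(op.rotation)[1] - 120) < 1e-6
                      and np.linalg.norm(op.translation) < 1e-9]
        identity = next(i for i, op in enumerate(model.symmetry_operators)
                        if op.is_identity)
        asm = expand_crystal_symmetry(model, [identity] + threefolds)
        assert len(asm.chains) == 3
        axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        dists = []
        for chain in asm.chains:
            p = chain.residues[0].atom("CA").position
            dists.append(np.linalg.norm(p - (p @ axis) * axis))
        assert np.ptp(dists) < 1e-9

    def test_rigid_copies_preserve_internal_distances(self, tmp_path, protomer):
        m = protomer.copy()
        m.cell = (100.0, 100.0, 100.0, 90.0, 90.0, 90.0)
        m.symmetry_operators = [SymmetryOperator(
            rotation_about_axis([1, 1, 1], 120.0), np.array([5.0, -2.0, 1.0]))]
        asm = expand_crystal_symmetry(m, [0])
        orig = protomer.coords()
        moved = asm.coords()
        d_orig = np.linalg.norm(orig[0] - orig[-1])
        d_moved = np.linalg.norm(moved[0] - moved[-1])
        assert d_moved == pytest.approx(d_orig, abs=1e-9)

    def test_missing_operators_is_capability_error(self, protomer):
        with pytest.raises(CapabilityError):
            expand_crystal_symmetry(protomer, [0])


class TestSequenceAndMass:
    def test_polyalanine_and_modified_residues(self):
        m = build_model([("ALA", i, [("CA", "C", [float(i), 0, 0])])
                        for i in range(1, 6)])
        assert extract_sequence(m, "A") == "AAAAA"
        assert extract_sequence(_toy_model(), "A") == "AMG"  # MSE -> M

    def test_unknown_chain(self):
        with pytest.raises(SelectionError):
            extract_sequence(_toy_model(), "Z")

    def test_glycine_free_amino_acid_mass(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_mass_additivity_over_multiplicity(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        assert molecular_weight(seq, 3) == pytest.approx(
            3 * molecular_weight(seq, 1), rel=1e-12)

    @pytest.mark.parametrize("bad", ["", "AB?Z"])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(ValidationError):
            molecular_weight(bad)

    def test_invalid_multiplicity(self):
        with pytest.raises(ValidationError):
            molecular_weight("AAA", 0)
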