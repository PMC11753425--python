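"""Domain centroids and symmetry distance classes."""

import numpy as np
import pytest

from trimergeo import (DomainDefinition, center_distance_matrix,
                       classify_distance_classes, compare_geometries,
                       domain_center)
from trimergeo.errors import (ClassificationError, ComparisonError,
                              GeometryError)
from trimergeo.model import build_model
from tests.conftest import random_rigid_motion


def _point_model(points, chain="A"):
    return build_model([("GLY", i + 1, [("CA", "C", p)])
                        for i, p in enumerate(points)], chain_id=chain)


class TestDomainCenter:
    def test_single_atom(self):
        m = _point_model([[1.0, 2.0, 3.0]])
        dc = domain_center(m, DomainDefinition("D", "A", [(1, 1)]))
        assert np.allclose(dc.center, [1, 2, 3])
        assert dc.atom_count == 1

    def test_waters_and_hydrogens_excluded(self):
        m = build_model([
            ("ALA", 1, [("CA", "C", [0.0, 0, 0]), ("H", "H", [90.0, 0, 0])]),
            ("HOH", 2, [("O", "O", [100.0, 0, 0])]),
            ("ALA", 3, [("CA", "C", [2.0, 0, 0])])])
        dc = domain_center(m, DomainDefinition("D", "A", [(1, 3)]))
        assert np.allclose(dc.center, [1.0, 0, 0])

    def test_ca_only_mode(self):
        m = build_model([("ALA", 1, [("CA", "C", [1.0, 0, 0]),
                                     ("CB", "C", [5.0, 0, 0])])])
        dc = domain_center(m, DomainDefinition("D", "A", [(1, 1)]),
                           atom_mode="ca_only")
        assert np.allclose(dc.center, [1.0, 0, 0])

    def test_empty_selection_is_error(self):
        m = _point_model([[0.0, 0, 0]])
        with pytest.raises(GeometryError):
            domain_center(m, DomainDefinition("D", "A", [(5, 9)]))

    def test_rigid_motion_equivariance_100_motions(self, protomer, exact_spec):
        blueprint = exact_spec.domains[0]
        ddef = DomainDefinition("D1", "A", [(blueprint.residue_number_start,
                                             blueprint.residue_number_end)])
        base = domain_center(protomer, ddef).center
        rng = np.random.default_rng(42)
        for _ in range(100):
            rot, tran = random_rigid_motion(rng)
            moved = domain_center(protomer.transformed(rot, tran), ddef).center
            assert np.linalg.norm(moved - (rot @ base + tran)) < 1e-9


class TestDistanceMatrix:
    def test_three_four_five(self):
        m = build_model([("GLY", 1, [("CA", "C", [0.0, 0, 0])]),
                         ("GLY", 2, [("CA", "C", [3.0, 4.0, 0])])])
        defs = [DomainDefinition("D1", "A", [(1, 1)]),
                DomainDefinition("D2", "A", [(2, 2)])]
        _, matrix = center_distance_matrix(m, defs)
        assert matrix[0, 1] == pytest.approx(5.0)
        assert matrix[0, 0] == 0.0
        assert np.allclose(matrix, matrix.T)

    def test_trimer_has_15_unordered_pairs(self, exact_assembly, exact_defs):
        _, matrix = center_distance_matrix(exact_assembly, exact_defs)
        assert matrix.shape == (6, 6)
        iu = np.triu_indices(6, k=1)
        assert len(matrix[iu]) == 15


class TestClassification:
    def test_partition_matches_brute_force_enumeration(self, exact_assembly,
                                                       exact_spec, exact_defs):
        """Independent oracle: centroids computed with raw numpy and pairs
        grouped by explicit chain-index arithmetic (chain k sits at
        position k by construction of the cyclic replicator)."""
        intervals = exact_spec.domain_intervals()
        centers = {}
        for cid in "ABC":
            chain = exact_assembly.chain(cid)
            for label, (lo, hi) in intervals.items():
                pts = [a.position for r in chain.residues
                       if lo <= r.number <= hi for a in r.atoms]
                centers[(label, cid)] = np.mean(pts, axis=0)
        pos = {"A": 0, "B": 1, "C": 2}
        oracle: dict[tuple, set] = {}
        keys = sorted(centers)
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                (la, ca), (lb, cb) = ka, kb
                if ca == cb and la == lb:
                    continue
                off = (pos[cb] - pos[ca]) % 3
                if la == lb:
                    key = (la, lb, min(off, 3 - off))
                elif la < lb:
                    key = (la, lb, off)
                else:
                    key = (lb, la, (3 - off) % 3)
                oracle.setdefault(key, set()).add(frozenset({ka, kb}))
        # orient primes: the closer cross class is the singly-primed one
        d_fwd = np.mean([np.linalg.norm(centers[a] - centers[b])
                         for a, b in [tuple(sorted(p)) for p in
                                      oracle[("D1", "D2", 1)]]])
        d_rev = np.mean([np.linalg.norm(centers[a] - centers[b])
                         for a, b in [tuple(sorted(p)) for p in
                                      oracle[("D1", "D2", 2)]]])
        if d_rev < d_fwd:
            flipped = {}
            for (a, b, off), v in oracle.items():
                off2 = (3 - off) % 3 if a != b else off
                flipped[(a, b, off2)] = v
            oracle = flipped

        summaries = classify_distance_classes(exact_assembly, exact_defs, 3)
        assert sum(len(s.members) for s in summaries) == 15
        from trimergeo.geometry import canonical_class_label
        oracle_by_label = {
            canonical_class_label(a, b, off): v
            for (a, b, off), v in oracle.items()}
        assert set(s.class_label for s in summaries) == set(oracle_by_label)
        for s in summaries:
            got = {frozenset(pair) for pair in _member_pairs(s, centers)}
            assert got == oracle_by_label[s.class_label]

    def test_rigid_motion_invariance(self, exact_assembly, exact_defs):
        rng = np.random.default_rng(7)
        rot, tran = random_rigid_motion(rng)
        moved = exact_assembly.transformed(rot, tran)
        base = classify_distance_classes(exact_assembly, exact_defs, 3)
        after = classify_distance_classes(moved, exact_defs, 3)
        for s0, s1 in zip(base, after):
            assert s0.class_label == s1.class_label
            assert s1.mean == pytest.approx(s0.mean, abs=1e-9)
            assert s1.rmsd == pytest.approx(s0.rmsd, abs=1e-9)

    def test_chain_relabelling_invariance(self, exact_assembly, exact_defs,
                                          exact_spec):
        relabelled = exact_assembly.copy()
        mapping = {"A": "B", "B": "C", "C": "A"}
        for chain in relabelled.chains:
            new_id = mapping[chain.id]
            chain.id = new_id
            for res in chain.residues:
                for atom in res.atoms:
                    atom.chain_id = new_id
        relabelled.chains.sort(key=lambda c: c.id)
        from trimergeo import definitions_for_assembly
        defs = definitions_for_assembly(exact_spec.domain_intervals(),
                                        relabelled.chain_ids)
        base = classify_distance_classes(exact_assembly, exact_defs, 3)
        after = classify_distance_classes(relabelled, defs, 3)
        for s0, s1 in zip(base, after):
            assert s0.class_label == s1.class_label
            assert s1.mean == pytest.approx(s0.mean, abs=1e-9)

    def test_non_cyclic_chains_rejected(self, protomer):
        from trimergeo.model import merge_models
        rng = np.random.default_rng(1)
        rot, tran = random_rigid_motion(rng)
        rot2, tran2 = random_rigid_motion(rng)
        bogus = merge_models([protomer, protomer.transformed(rot, tran),
                              protomer.transformed(rot2, tran2)])
        defs = [DomainDefinition("D1", cid, [(92, 131)])
                for cid in bogus.chain_ids]
        with pytest.raises(ClassificationError):
            classify_distance_classes(bogus, defs, 3)


def _member_pairs(summary, centers):
    """Recover which (label, chain) centre pair each member distance is,
    by matching the distance against the exact centre table."""
    pairs = []
    keys = sorted(centers)
    for (ca, cb), dist in summary.members:
        match = None
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                if {ka[1], kb[1]} != {ca, cb}:
                    continue
                if abs(np.linalg.norm(centers[ka] - centers[kb]) - dist) < 1e-9:
                    match = (ka, kb)
        assert match is not None
        pairs.append(match)
    return pairs


class TestCompareGeometries:
    def test_identical_summaries_ratio_one(self, exact_assembly, exact_defs):
        s = classify_distance_classes(exact_assembly, exact_defs, 3)
        table = compare_geometries(s, s)
        assert np.allclose(table["ratio"], 1.0)
        assert np.allclose(table["delta"], 0.0)

    def test_global_scaling_gives_exact_ratio(self, exact_assembly, exact_defs):
        scaled = exact_assembly.copy()
        scaled.map_positions(lambda p: 0.9 * p)
        s0 = classify_distance_classes(exact_assembly, exact_defs, 3)
        s1 = classify_distance_classes(scaled, exact_defs, 3)
        table = compare_geometries(s0, s1)
        assert np.allclose(table["ratio"], 0.9, atol=1e-9)

    def test_label_mismatch_rejected(self, exact_assembly, exact_defs):
        s = classify_distance_classes(exact_assembly, exact_defs, 3)
        with pytest.raises(ComparisonError):
            compare_geometries(s, s[:-1])
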