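"""Kabsch superposition, TM-score and the structure-only aligner."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from trimergeo import (align_structures, compare_models, default_spec, kabsch,
                       make_protomer, select, tm_d0, tm_score_coords)
from trimergeo.errors import AlignmentError, SuperpositionError
from trimergeo.model import build_model, merge_models
from tests.conftest import random_rigid_motion


def _random_walk(n, seed, scale=2.0):
    rng = np.random.default_rng(seed)
    return np.cumsum(rng.normal(scale=scale, size=(n, 3)), axis=0)


class TestKabsch:
    def test_self_superposition_is_identity(self):
        a = _random_walk(10, 0)
        sup = kabsch(a, a)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_random_rigid_motion(self):
        rng = np.random.default_rng(11)
        a = _random_walk(25, 1)
        for _ in range(10):
            rot, tran = random_rigid_motion(rng)
            sup = kabsch(a, a @ rot.T + tran)
            assert sup.rmsd == pytest.approx(0.0, abs=1e-8)
            assert np.allclose(sup.rotation, rot, atol=1e-9)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_matches_rotational_grid_brute_force_on_4_point_toys(self):
        """Oracle: exhaustive search over ~2000 axes x 2-degree angle steps
        with optimal translation; the Kabsch optimum must match the grid
        minimum to within grid resolution (and never exceed it)."""
        angles = np.deg2rad(np.arange(0, 180, 2))
        n_ax = 2000
        k = np.arange(n_ax) + 0.5
        phi = np.arccos(1 - 2 * k / n_ax)
        th = np.pi * (1 + 5 ** 0.5) * k
        axes = np.column_stack([np.cos(th) * np.sin(phi),
                                np.sin(th) * np.sin(phi), np.cos(phi)])
        for seed in (3, 5):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=(4, 3)) * 2
            b = rng.normal(size=(4, 3)) * 2
            sup = kabsch(a, b)
            a0, b0 = a - a.mean(0), b - b.mean(0)
            best = np.inf
            for ax in axes:
                rots = Rotation.from_rotvec(np.outer(angles, ax)).as_matrix()
                moved = np.einsum("rij,nj->rni", rots, a0)
                rms = np.sqrt(((moved - b0) ** 2).sum(-1).mean(-1))
                best = min(best, rms.min())
            assert sup.rmsd <= best + 1e-12
            assert best - sup.rmsd < 0.05

    def test_too_few_or_degenerate_pairs_rejected(self):
        with pytest.raises(SuperpositionError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(SuperpositionError):
            kabsch(line, line)


class TestTmScore:
    def test_d0_formula_and_floor(self):
        assert tm_d0(10) == 0.5
        assert tm_d0(21) == 0.5
        assert tm_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8)

    def test_self_alignment_scores_one(self):
        a = _random_walk(40, 2)
        score, _ = tm_score_coords(a, a, 40)
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_all_distances_at_d0_gives_half(self):
        # the TM kernel itself: sum 1/(1+(d/d0)^2)/L with d = d0 everywhere
        from trimergeo.superpose import _tm_from_distances
        l_norm = 50
        d = np.full(l_norm, tm_d0(l_norm))
        assert _tm_from_distances(d, l_norm) == pytest.approx(0.5)

    def test_empty_alignment_rejected(self):
        with pytest.raises(AlignmentError):
            tm_score_coords(np.empty((0, 3)), np.empty((0, 3)), 1)

    def test_dominates_contiguous_subset_oracle(self):
        """The iterative refinement must reach at least the best score
        obtainable from a Kabsch superposition of any contiguous pair
        subset of length >= 5 (exhaustive enumeration)."""
        for seed in (0, 4, 5):
            a = _random_walk(30, seed)
            b = _random_walk(30, seed + 100)
            l_norm, d0 = 30, tm_d0(30)
            best = 0.0
            for length in range(5, 31):
                for start in range(0, 31 - length):
                    window = slice(start, start + length)
                    try:
                        sup = kabsch(a[window], b[window])
                    except SuperpositionError:
                        continue
                    d = np.linalg.norm(sup.apply(a) - b, axis=1)
                    best = max(best, float(np.sum(1 / (1 + (d / d0) ** 2)) / l_norm))
            ours, _ = tm_score_coords(a, b, l_norm)
            assert ours >= best - 1e-9

    def test_swapping_inputs_with_fixed_l_norm_changes_nothing(self):
        a = _random_walk(30, 8)
        b = _random_walk(30, 9)
        s_ab, _ = tm_score_coords(a, b, 30)
        s_ba, _ = tm_score_coords(b, a, 30)
        assert s_ab == pytest.approx(s_ba, abs=1e-9)


class TestAligner:
    def test_rigid_copy_fully_aligned(self, protomer):
        rng = np.random.default_rng(21)
        rot, tran = random_rigid_motion(rng)
        aln = align_structures(protomer, protomer.transformed(rot, tran))
        n_res = len(protomer.chains[0].residues)
        assert aln.n_pairs == n_res
        assert aln.tm_score == pytest.approx(1.0, abs=1e-6)
        assert aln.identity == pytest.approx(1.0)
        assert aln.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_pairs_are_strictly_increasing(self, protomer):
        spec = default_spec(seed=5)
        other = make_protomer(spec)
        aln = align_structures(protomer, other)
        nums_a = [p[0][1] for p in aln.pairs]
        nums_b = [p[1][1] for p in aln.pairs]
        assert nums_a == sorted(nums_a) and len(set(nums_a)) == len(nums_a)
        assert nums_b == sorted(nums_b) and len(set(nums_b)) == len(nums_b)

    def test_tm_invariant_under_rigid_motion_of_either_input(self, protomer):
        spec = default_spec(seed=6)
        other = make_protomer(spec)
        base = align_structures(protomer, other).tm_score
        rng = np.random.default_rng(31)
        rot, tran = random_rigid_motion(rng)
        moved = align_structures(protomer.transformed(rot, tran), other)
        assert moved.tm_score == pytest.approx(base, abs=1e-6)

    def test_expected_tm_decreases_with_noise(self, protomer):
        """Monotonicity (stochastic): the mean TM against a noisy copy does
        not increase with the noise level."""
        means = []
        for sigma in (0.0, 1.0, 3.0):
            scores = []
            for seed in range(3):
                rng = np.random.default_rng(seed)
                noisy = protomer.copy()
                noisy.map_positions(
                    lambda p: p + rng.normal(scale=sigma, size=3))
                scores.append(align_structures(protomer, noisy).tm_score)
            means.append(np.mean(scores))
        assert means[0] >= means[1] >= means[2]

    def test_too_small_input_rejected(self):
        tiny = build_model([("ALA", i, [("CA", "C", [float(i), 0, 0])])
                           for i in range(5)])
        with pytest.raises(AlignmentError):
            align_structures(tiny, tiny)


class TestCompareModels:
    def test_trimer_self_comparison_is_one(self, exact_assembly, exact_spec):
        iv = exact_spec.domain_intervals()
        row = compare_models(exact_assembly, exact_assembly, "trimer", iv, iv)
        assert row["tm_mean"] == pytest.approx(1.0, abs=1e-6)
        assert row["n_comparisons"] == 1

    def test_average_equals_manual_enumeration(self, exact_assembly,
                                               exact_spec):
        """Oracle: build each equivalent D1 sub-model by hand and average
        the pairwise alignment scores directly."""
        iv = exact_spec.domain_intervals()
        row = compare_models(exact_assembly, exact_assembly, "D1", iv, iv,
                             order=3)
        subs = [select(exact_assembly, cid, [iv["D1"]]) for cid in "ABC"]
        scores = [align_structures(sa, sb).tm_score
                  for sa in subs for sb in subs]
        assert row["n_comparisons"] == 9
        assert row["tm_mean"] == pytest.approx(np.mean(scores), abs=1e-9)

    def test_pair_prime_uses_interacting_neighbour(self, exact_assembly,
                                                   exact_spec):
        iv = exact_spec.domain_intervals()
        row = compare_models(exact_assembly, exact_assembly, "pair_prime",
                             iv, iv, order=3)
        assert row["tm_mean"] == pytest.approx(1.0, abs=1e-6)
        assert row["n_comparisons"] == 9
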