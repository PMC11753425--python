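"""Rigid superposition (Kabsch), TM-score and sequence-independent alignment.

The aligner fills the role of a structure-only alignment tool: it ignores
residue identity entirely and pairs residues by spatial proximity after an
optimal rigid superposition.  Candidate pairings are seeded by gapless
threading at a range of sequence offsets plus fragment-pair superpositions,
and each seed is refined by alternating Kabsch superposition on the current
pairs with a dynamic-programming re-pairing whose match score is
``1 / (1 + (d_ij / d0)^2)`` (the TM-score kernel) and whose gap penalty is
-0.6 with free end gaps.  The best result by TM-score is returned;
structure-derived sequence identity is computed over the final pairs only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .errors import AlignmentError, SuperpositionError
from .model import StructureModel, three_to_one

__all__ = ["Superposition", "StructureAlignment", "kabsch", "tm_d0",
           "tm_score", "tm_score_coords", "align_structures", "compare_models"]

GAP_PENALTY = 0.6  # DP gap penalty (TM-align convention), end gaps free
MIN_ALIGN_RESIDUES = 15


@dataclass
class Superposition:
    """Optimal proper rigid motion x -> R x + t of A onto B."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_paired: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares superposition of paired coordinates (reflections
    excluded).  Requires >= 3 non-collinear pairs."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise SuperpositionError("paired coordinate arrays must both be (N, 3)")
    n = a.shape[0]
    if n < 3:
        raise SuperpositionError(f"need >= 3 pairs, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    span = np.linalg.norm(a0, axis=1).max()
    if span < 1e-9 or s[1] < 1e-9 * max(s[0], 1.0):
        raise SuperpositionError("degenerate (collinear or coincident) geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    tran = cb - rot @ ca
    moved = a @ rot.T + tran
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return Superposition(rot, tran, rmsd, n)


def tm_d0(l_norm: int) -> float:
    """TM-score distance scale: 1.24 (L-15)^(1/3) - 1.8, floored at 0.5."""
    if l_norm <= 21:
        return 0.5
    return max(0.5, 1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8)


def _tm_from_distances(d: np.ndarray, l_norm: int) -> float:
    d0 = tm_d0(l_norm)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)


def tm_score_coords(coords_a: np.ndarray, coords_b: np.ndarray,
                    l_norm: int | None = None,
                    ) -> tuple[float, Superposition]:
    """TM-score of a fixed residue pairing, maximised over superpositions.

    Iterative subset refinement: seeds are contiguous windows of the
    pairing (full length down to 4 pairs); each seed is superposed by
    Kabsch, the TM-score over *all* pairs evaluated, and the subset
    re-grown from pairs within the inclusion cutoff until stable.  Returns
    the best score and the superposition that achieves it.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    n = a.shape[0]
    if n == 0:
        raise AlignmentError("empty alignment")
    l_norm = int(l_norm) if l_norm else n
    if l_norm < 1:
        raise AlignmentError("normalization length must be >= 1")
    d0 = tm_d0(l_norm)
    best_tm, best_sup = -1.0, None

    lengths: list[int] = []
    length = n
    while length >= 4:
        lengths.append(length)
        length //= 2
    if not lengths:
        lengths = [n]
    for length in lengths:
        step = max(1, length // 2)
        for start in range(0, n - length + 1, step):
            subset = np.arange(start, start + length)
            prev: frozenset | None = None
            for _ in range(20):
                if subset.size < 3:
                    break
                try:
                    sup = kabsch(a[subset], b[subset])
                except SuperpositionError:
                    break
                d = np.linalg.norm(sup.apply(a) - b, axis=1)
                tm = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)
                if tm > best_tm:
                    best_tm, best_sup = tm, sup
                cut = max(d0, 1.0)
                new = np.flatnonzero(d < cut)
                while new.size < 3 and cut < 50.0:
                    cut += 0.5
                    new = np.flatnonzero(d < cut)
                key = frozenset(new.tolist())
                if prev is not None and key == prev:
                    break
                prev = key
                subset = new
    if best_sup is None:  # degenerate everywhere: fall back to raw pairing
        raise AlignmentError("TM-score refinement failed on degenerate input")
    return best_tm, best_sup


@dataclass
class StructureAlignment:
    """Residue-level structural alignment of two models."""

    pairs: list[tuple[tuple, tuple]]          # ((chain, num, icode, name), ...)
    coords_a: np.ndarray                      # paired CA coordinates of A
    coords_b: np.ndarray
    l_norm: int
    tm_score: float
    identity: float
    superposition: Superposition
    per_pair_distance: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.per_pair_distance is None:
            moved = self.superposition.apply(self.coords_a)
            self.per_pair_distance = np.linalg.norm(moved - self.coords_b, axis=1)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def rmsd(self) -> float:
        return float(np.sqrt(np.mean(self.per_pair_distance ** 2)))


def tm_score(alignment: StructureAlignment) -> float:
    """TM-score of an alignment (recomputed by subset refinement)."""
    score, _ = tm_score_coords(alignment.coords_a, alignment.coords_b,
                               alignment.l_norm)
    return score


@njit(cache=True)
def _dp_trace(score: np.ndarray, gap: float):  # pragma: no cover - numba
    n, m = score.shape
    h = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 diag, 2 up, 3 left
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = h[i - 1, j - 1] + score[i - 1, j - 1]
            up = h[i - 1, j] - (gap if j != m else 0.0)
            left = h[i, j - 1] - (gap if i != n else 0.0)
            best = diag
            p = 1
            if up > best:
                best, p = up, 2
            if left > best:
                best, p = left, 3
            h[i, j] = best
            ptr[i, j] = p
    # free end gaps are encoded by zero-cost moves along the last row/column
    out_a = np.empty(min(n, m), dtype=np.int64)
    out_b = np.empty(min(n, m), dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 0 and j > 0:
        p = ptr[i, j]
        if p == 1:
            out_a[k] = i - 1
            out_b[k] = j - 1
            k += 1
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return out_a[:k][::-1], out_b[:k][::-1]


def _residue_table(model: StructureModel):
    ids, letters, coords = [], [], []
    for chain in model.chains:
        for res in chain.residues:
            ca = res.atom("CA")
            if res.is_water or ca is None:
                continue
            ids.append((chain.id, res.number, res.insertion_code, res.name))
            letters.append(three_to_one(res.name))
            coords.append(ca.position)
    if not coords:
        return ids, letters, np.empty((0, 3))
    return ids, letters, np.vstack(coords)


def _refine_seed(a: np.ndarray, b: np.ndarray, pairs_a: np.ndarray,
                 pairs_b: np.ndarray, d0: float,
                 max_iter: int = 30) -> tuple[np.ndarray, np.ndarray] | None:
    seen: set[frozenset] = set()
    for _ in range(max_iter):
        if pairs_a.size < 3:
            return None
        try:
            sup = kabsch(a[pairs_a], b[pairs_b])
        except SuperpositionError:
            return None
        moved = sup.apply(a)
        d2 = ((moved[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1)
        score = 1.0 / (1.0 + d2 / (d0 * d0))
        new_a, new_b = _dp_trace(score, GAP_PENALTY)
        key = frozenset(zip(new_a.tolist(), new_b.tolist()))
        if key in seen:
            pairs_a, pairs_b = new_a, new_b
            break
        seen.add(key)
        pairs_a, pairs_b = new_a, new_b
    return pairs_a, pairs_b


def align_structures(model_a: StructureModel, model_b: StructureModel,
                     l_norm: int | None = None) -> StructureAlignment:
    """Sequence-independent pairwise structural alignment (CA based).

    By default the TM-score is normalised by the length of the shorter
    structure.
    """
    ids_a, seq_a, a = _residue_table(model_a)
    ids_b, seq_b, b = _residue_table(model_b)
    n, m = len(a), len(b)
    if n < MIN_ALIGN_RESIDUES or m < MIN_ALIGN_RESIDUES:
        raise AlignmentError(
            f"need >= {MIN_ALIGN_RESIDUES} CA atoms in both structures "
            f"(got {n} and {m})")
    l_norm = int(l_norm) if l_norm else min(n, m)
    d0 = tm_d0(l_norm)

    seeds: list[tuple[np.ndarray, np.ndarray]] = []
    # gapless threading over sequence offsets
    offsets = range(-(m - MIN_ALIGN_RESIDUES), n - MIN_ALIGN_RESIDUES + 1)
    stride = max(1, len(offsets) // 40)
    for off in list(offsets)[::stride]:
        ia = np.arange(max(0, off), min(n, m + off))
        ib = ia - off
        seeds.append((ia, ib))
    # fragment-pair seeds
    frag = 15
    for sa in range(0, n - frag + 1, max(1, n // 6)):
        for sb in range(0, m - frag + 1, max(1, m // 6)):
            seeds.append((np.arange(sa, sa + frag), np.arange(sb, sb + frag)))

    best = None  # (tm, pairs_a, pairs_b)
    for ia, ib in seeds:
        refined = _refine_seed(a, b, ia, ib, d0)
        if refined is None or refined[0].size < 3:
            continue
        pa, pb = refined
        try:
            tm, _ = tm_score_coords(a[pa], b[pb], l_norm)
        except AlignmentError:
            continue
        if best is None or tm > best[0]:
            best = (tm, pa, pb)
    if best is None:
        raise AlignmentError("no alignment seed could be refined")

    tm, pa, pb = best
    _, sup = tm_score_coords(a[pa], b[pb], l_norm)
    matches = sum(1 for i, j in zip(pa, pb)
                  if seq_a[i] == seq_b[j] and seq_a[i] != "X")
    identity = matches / len(pa) if len(pa) else 0.0
    return StructureAlignment(
        pairs=[(ids_a[i], ids_b[j]) for i, j in zip(pa, pb)],
        coords_a=a[pa], coords_b=b[pb], l_norm=l_norm,
        tm_score=tm, identity=identity, superposition=sup)


# ----------------------------------------------------------------------
# model-level comparison (average TM over equivalent sub-models)
# ----------------------------------------------------------------------

def _submodels(assembly: StructureModel, intervals: dict[str, tuple[int, int]],
               mode: str, order: int) -> list[StructureModel]:
    from .geometry import definitions_for_assembly, domain_center
    from .model import merge_models
    from .structure_io import select

    labels = sorted(intervals)
    chain_ids = assembly.chain_ids
    if mode == "trimer":
        return [assembly]
    if mode in labels:  # a single domain, one sub-model per chain
        return [select(assembly, cid, [intervals[mode]]) for cid in chain_ids]
    first, second = labels[0], labels[1]
    if mode == "pair_same":
        return [merge_models(
            [select(assembly, cid, [intervals[first]]),
             select(assembly, cid, [intervals[second]])], relabel=False)
            for cid in chain_ids]
    if mode == "pair_prime":
        # concatenate the first domain of each protomer with the second
        # domain of the protomer whose copy of it sits closest (the
        # interacting neighbour)
        defs = definitions_for_assembly(intervals, chain_ids)
        centers = {(d.label, d.chain_id): domain_center(assembly, d).center
                   for d in defs}
        out = []
        for cid in chain_ids:
            partner = min(
                (c for c in chain_ids if c != cid),
                key=lambda c: np.linalg.norm(centers[(first, cid)]
                                             - centers[(second, c)]))
            out.append(merge_models(
                [select(assembly, cid, [intervals[first]]),
                 select(assembly, partner, [intervals[second]])],
                relabel=False))
        return out
    raise AlignmentError(f"unknown comparison mode {mode!r}")


def compare_models(assembly_a: StructureModel, assembly_b: StructureModel,
                   mode: str, intervals_a: dict[str, tuple[int, int]],
                   intervals_b: dict[str, tuple[int, int]],
                   order: int = 3) -> dict:
    """Average TM-score over all pairings of equivalent sub-models.

    ``mode`` is a domain label (single domain), "pair_same" (both domains
    of one protomer), "pair_prime" (first domain of one protomer
    concatenated with the interacting second domain of the neighbouring
    protomer) or "trimer".
    """
    subs_a = _submodels(assembly_a, intervals_a, mode, order)
    subs_b = _submodels(assembly_b, intervals_b, mode, order)
    scores, rmsds, npairs = [], [], []
    for sa in subs_a:
        for sb in subs_b:
            aln = align_structures(sa, sb)
            scores.append(aln.tm_score)
            rmsds.append(aln.rmsd)
            npairs.append(aln.n_pairs)
    return {
        "mode": mode,
        "tm_mean": float(np.mean(scores)),
        "tm_values": scores,
        "rmsd_mean": float(np.mean(rmsds)),
        "n_pairs_mean": float(np.mean(npairs)),
        "n_comparisons": len(scores),
    }
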