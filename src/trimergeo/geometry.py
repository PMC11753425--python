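"""Domain centroids and symmetry-equivalent centre-centre distance classes.

For a Cn assembly of m-domain protomers there are ``n*m`` domain centroids
and ``C(n*m, 2)`` unordered centre pairs.  Pairs related by the cyclic
symmetry are geometrically equivalent; grouping them and summarising each
class as mean +/- RMSD is the fingerprint used to compare trimer
architectures.  Class labels use the field's prime notation: D1:D2 is the
pair within one protomer, D1:D2' pairs a domain with the next protomer
around the axis, D1:D2'' with the one after that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ClassificationError, ComparisonError, GeometryError
from .model import StructureModel
from .structure_io import select

__all__ = ["DomainDefinition", "DomainCenter", "DistanceClassSummary",
           "domain_center", "center_distance_matrix",
           "classify_distance_classes", "compare_geometries",
           "canonical_class_label", "definitions_for_assembly"]

_PRIMES = {0: "", 1: "′", 2: "″", 3: "‴"}


def _prime_suffix(k: int) -> str:
    return _PRIMES.get(k, f"({k}′)")


def canonical_class_label(label_a: str, label_b: str, offset: int) -> str:
    """Canonical class label for a domain pair separated by ``offset``
    protomer steps around the cyclic axis (labels sorted, primes on the
    second label)."""
    return f"{label_a}:{label_b}{_prime_suffix(offset)}"


@dataclass
class DomainDefinition:
    """A named set of inclusive residue intervals on one chain."""

    label: str
    chain_id: str
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise GeometryError(f"domain {self.label}: no intervals")
        for start, end in self.intervals:
            if start > end:
                raise GeometryError(
                    f"domain {self.label}: malformed interval [{start}, {end}]")


@dataclass
class DomainCenter:
    label: str
    chain_id: str
    center: np.ndarray
    atom_count: int


@dataclass
class DistanceClassSummary:
    """One symmetry-equivalence class of centre-centre distances."""

    class_label: str
    members: list[tuple[tuple[str, str], float]]
    mean: float = field(init=False)
    rmsd: float = field(init=False)

    def __post_init__(self) -> None:
        values = np.array([d for _, d in self.members], dtype=float)
        self.mean = float(values.mean())
        self.rmsd = float(np.sqrt(np.mean((values - self.mean) ** 2)))


def definitions_for_assembly(intervals: dict[str, Sequence[tuple[int, int]] | tuple[int, int]],
                             chain_ids: Sequence[str]) -> list[DomainDefinition]:
    """Replicate per-protomer domain intervals over every chain of an
    assembly.  ``intervals`` maps label -> (start, end) or list thereof."""
    defs = []
    for chain_id in chain_ids:
        for label, iv in intervals.items():
            ivs = [tuple(iv)] if np.isscalar(iv[0]) else [tuple(x) for x in iv]
            defs.append(DomainDefinition(label, chain_id, ivs))
    return defs


def domain_center(model: StructureModel, definition: DomainDefinition,
                  atom_mode: str = "all_heavy") -> DomainCenter:
    """Unweighted arithmetic mean of the selected atoms' coordinates.

    ``atom_mode`` is ``all_heavy`` (every non-hydrogen, non-water atom) or
    ``ca_only``.  Unmodelled residues are simply absent from the mean.
    """
    sub = select(model, definition.chain_id, definition.intervals)
    if atom_mode == "all_heavy":
        atoms = sub.atoms(heavy_only=True, exclude_water=True)
    elif atom_mode == "ca_only":
        atoms = [a for a in sub.iter_atoms(exclude_water=True)
                 if a.atom_name == "CA"]
    else:
        raise GeometryError(f"unknown atom_mode {atom_mode!r}")
    if not atoms:
        raise GeometryError(
            f"domain {definition.label} on chain {definition.chain_id}: "
            "empty selection")
    coords = np.vstack([a.position for a in atoms])
    return DomainCenter(definition.label, definition.chain_id,
                        coords.mean(axis=0), len(atoms))


def center_distance_matrix(assembly: StructureModel,
                           definitions: Sequence[DomainDefinition],
                           atom_mode: str = "all_heavy",
                           ) -> tuple[list[DomainCenter], np.ndarray]:
    """All centre-centre distances between the defined domains.

    Returns the resolved centres (in definition order) and the symmetric
    distance matrix with zero diagonal.
    """
    centers = [domain_center(assembly, d, atom_mode) for d in definitions]
    if len(centers) < 2:
        raise GeometryError("need at least two domains for a distance matrix")
    pts = np.vstack([c.center for c in centers])
    diff = pts[:, None, :] - pts[None, :, :]
    return centers, np.sqrt((diff ** 2).sum(axis=-1))


# ----------------------------------------------------------------------
# cyclic chain order
# ----------------------------------------------------------------------

def _paired_ca(chain_a, chain_b) -> tuple[np.ndarray, np.ndarray]:
    """CA coordinates paired by (residue number, insertion code)."""
    index_b = {(r.number, r.insertion_code): r for r in chain_b.residues
               if r.atom("CA") is not None}
    pa, pb = [], []
    for res in chain_a.residues:
        ca = res.atom("CA")
        other = index_b.get((res.number, res.insertion_code))
        if ca is not None and other is not None and other.atom("CA") is not None:
            pa.append(ca.position)
            pb.append(other.atom("CA").position)
    if len(pa) < 3:
        raise ClassificationError("chains share fewer than 3 CA positions")
    return np.vstack(pa), np.vstack(pb)


def cyclic_chain_positions(assembly: StructureModel, order: int,
                           chain_ids: Sequence[str] | None = None) -> dict[str, int]:
    """Position of each chain around the cyclic axis (0 .. order-1).

    Chain order is determined from the rotations that best superpose the
    first chain onto each of the others — never from alphabetical
    assumptions.  Raises :class:`ClassificationError` when the chains do
    not form a single cyclic orbit.
    """
    from .superpose import kabsch  # local import to avoid a cycle

    ids = list(chain_ids) if chain_ids is not None else assembly.chain_ids
    if len(ids) != order:
        raise ClassificationError(
            f"expected {order} chains for a C{order} assembly, got {len(ids)}")
    if order == 1:
        return {ids[0]: 0}
    ref = assembly.chain(ids[0])
    step = 2.0 * np.pi / order
    rotvecs = {}
    for cid in ids[1:]:
        pa, pb = _paired_ca(ref, assembly.chain(cid))
        sup = kabsch(pa, pb)
        from scipy.spatial.transform import Rotation
        rotvecs[cid] = Rotation.from_matrix(sup.rotation).as_rotvec()
    # global axis: the rotation axis taking chain 0 to the second chain
    axis = rotvecs[ids[1]]
    norm = np.linalg.norm(axis)
    if norm < 1e-8:
        raise ClassificationError("chains related by identity, not a rotation")
    axis = axis / norm
    positions = {ids[0]: 0}
    used = {0}
    for cid in ids[1:]:
        rv = rotvecs[cid]
        angle = np.linalg.norm(rv)
        cos_axis = abs(rv @ axis) / angle if angle > 1e-12 else 0.0
        if cos_axis < 0.9:
            raise ClassificationError(
                f"chain {cid} is not related to chain {ids[0]} by a rotation "
                "about the common cyclic axis")
        signed = angle if rv @ axis >= 0 else -angle
        pos = int(round((signed % (2.0 * np.pi)) / step)) % order
        residual = abs((signed % (2.0 * np.pi)) - pos * step)
        residual = min(residual, 2.0 * np.pi - residual)
        if residual > 0.2:
            raise ClassificationError(
                f"chain {cid}: rotation angle is not a multiple of "
                f"360/{order} degrees (residual {np.degrees(residual):.1f} deg)")
        if pos in used or pos == 0:
            raise ClassificationError(
                f"chains {ids} do not form a single C{order} orbit "
                f"(chain {cid} maps to position {pos})")
        positions[cid] = pos
        used.add(pos)
    return positions


def classify_distance_classes(assembly: StructureModel,
                              definitions: Sequence[DomainDefinition],
                              order: int,
                              atom_mode: str = "all_heavy",
                              ) -> list[DistanceClassSummary]:
    """Group all centre-centre distances into symmetry-equivalence classes.

    Every unordered pair of domain centres belongs to exactly one class,
    keyed by the unordered label pair and the cyclic chain offset.  The
    prime orientation is canonicalised so that, for the first cross-domain
    pair, the singly-primed class is the closer one (the interacting
    interface); cyclically relabelling the chains therefore does not change
    the summaries.
    """
    centers, matrix = center_distance_matrix(assembly, definitions, atom_mode)
    chain_ids = sorted({c.chain_id for c in centers},
                       key=lambda cid: assembly.chain_ids.index(cid))
    positions = cyclic_chain_positions(assembly, order, chain_ids)

    def classify(flip: bool) -> dict[tuple[str, str, int], list]:
        classes: dict[tuple[str, str, int], list] = {}
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                ci, cj = centers[i], centers[j]
                if ci.chain_id == cj.chain_id and ci.label == cj.label:
                    continue
                off = (positions[cj.chain_id] - positions[ci.chain_id]) % order
                if flip:
                    off = (order - off) % order
                la, lb = ci.label, cj.label
                if la == lb:
                    key = (la, lb, min(off, (order - off) % order))
                elif la < lb:
                    key = (la, lb, off)
                else:
                    key = (lb, la, (order - off) % order)
                classes.setdefault(key, []).append(
                    ((ci.chain_id, cj.chain_id), float(matrix[i, j])))
        return classes

    classes = classify(flip=False)
    cross = sorted({(a, b) for a, b, _ in classes if a != b})
    if cross and order > 2:
        a, b = cross[0]
        mean_fwd = np.mean([d for _, d in classes.get((a, b, 1), [(None, np.inf)])])
        mean_rev = np.mean([d for _, d in classes.get((a, b, order - 1),
                                                      [(None, np.inf)])])
        if mean_rev < mean_fwd:
            classes = classify(flip=True)

    summaries = [
        DistanceClassSummary(canonical_class_label(a, b, off), members)
        for (a, b, off), members in classes.items()]
    summaries.sort(key=lambda s: s.class_label)
    return summaries


def summaries_as_frame(summaries: Sequence[DistanceClassSummary]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of distance-class summaries."""
    return pd.DataFrame({
        "class": [s.class_label for s in summaries],
        "members": [len(s.members) for s in summaries],
        "mean_A": [s.mean for s in summaries],
        "rmsd_A": [s.rmsd for s in summaries],
    })


def compare_geometries(summary_a: Sequence[DistanceClassSummary],
                       summary_b: Sequence[DistanceClassSummary],
                       ) -> pd.DataFrame:
    """Per-class comparison table: mean_a, mean_b, difference and b/a ratio.

    Used to quantify how much tighter one trimer is than another, class by
    class.  Requires identical class labels on both sides.
    """
    by_a = {s.class_label: s for s in summary_a}
    by_b = {s.class_label: s for s in summary_b}
    if set(by_a) != set(by_b):
        raise ComparisonError(
            f"class labels differ: {sorted(set(by_a) ^ set(by_b))}")
    labels = sorted(by_a)
    return pd.DataFrame({
        "class": labels,
        "mean_a": [by_a[l].mean for l in labels],
        "mean_b": [by_b[l].mean for l in labels],
        "delta": [by_b[l].mean - by_a[l].mean for l in labels],
        "ratio": [by_b[l].mean / by_a[l].mean for l in labels],
    })
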