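"""Synthetic Cn assemblies of two-domain protomers with known ground truth.

The generator emulates the quaternary architecture under study — protomers
of two globular domains joined by an extended linker, arranged with exact
cyclic symmetry — using pseudo-atom clouds rather than real stereochemistry.
Every geometric quantity the analysis modules compute (domain centroids,
symmetry-equivalent distance classes, interface contacts, engineered
disulfide geometry) is therefore known in closed form, which is what makes
the downstream stages testable without any deposited structure.

Randomness is governed by a single integer seed.  Draw order is fixed and
documented: for each domain, in blueprint order, the CA directions
(``residue_count x 3`` standard normals) are drawn first, then the radial
factors (``residue_count`` uniforms); post-replication coordinate noise
uses an independent stream derived from the same seed and is drawn atom by
atom in assembly order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import SpecError
from .model import AtomRecord, Chain, Residue, StructureModel
from .structure_io import build_cyclic_assembly, rotation_about_axis

__all__ = ["DomainBlueprint", "AssemblySpec", "make_protomer",
           "make_cn_assembly", "default_spec", "expected_center_distances",
           "ground_truth"]

# local offsets (A) of the backbone pseudo-atoms relative to each CA
_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.30, 0.00]),
    "C": np.array([1.20, 0.30, 0.00]),
    "O": np.array([1.90, 1.30, 0.00]),
    "CB": np.array([0.00, -0.60, 1.40]),
}
_ELEMENTS = {"N": "N", "C": "C", "O": "O", "CB": "C", "CA": "C", "SG": "S"}

#: Sgamma-Sgamma separation of an ideal disulfide bridge (A)
DISULFIDE_SG_SG = 2.05
#: Cbeta-Cbeta separation engineered across the interface (A)
ENGINEERED_CB_CB = 4.20


@dataclass
class DomainBlueprint:
    """One pseudo-domain: a seeded atom cloud about a prescribed centroid."""

    label: str
    residue_count: int
    center: np.ndarray
    radius: float
    residue_number_start: int

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.residue_count < 1:
            raise SpecError(f"domain {self.label}: residue_count must be >= 1")
        if self.radius <= 0:
            raise SpecError(f"domain {self.label}: radius must be > 0")

    @property
    def residue_number_end(self) -> int:
        return self.residue_number_start + self.residue_count - 1


@dataclass
class AssemblySpec:
    """Full recipe for a Cn assembly with known ground truth."""

    order: int = 3
    axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    domains: list[DomainBlueprint] = field(default_factory=list)
    linker_length: int = 0
    noise_sigma: float = 0.0
    seed: int = 0
    engineered_cys: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        if self.order < 2:
            raise SpecError(f"cyclic order must be >= 2, got {self.order}")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be >= 0")
        if not self.domains:
            raise SpecError("at least one domain blueprint required")
        ordered = sorted(self.domains, key=lambda d: d.residue_number_start)
        for prev, nxt in zip(ordered, ordered[1:]):
            gap = nxt.residue_number_start - prev.residue_number_end - 1
            if gap < 0:
                raise SpecError(
                    f"domains {prev.label} and {nxt.label} overlap in "
                    "residue numbering")
            if self.linker_length > gap:
                raise SpecError(
                    f"linker of {self.linker_length} residues does not fit "
                    f"between {prev.label} (ends {prev.residue_number_end}) "
                    f"and {nxt.label} (starts {nxt.residue_number_start})")
        self.domains = ordered
        if self.engineered_cys is not None:
            if len(self.engineered_cys) > 2:
                raise SpecError("engineered_cys takes at most two residues")
            labels = {d.label for d in self.domains}
            for lab, off in self.engineered_cys:
                dom = self.domain(lab)
                if lab not in labels:
                    raise SpecError(f"engineered_cys: unknown domain {lab!r}")
                if not 0 <= off < dom.residue_count:
                    raise SpecError(
                        f"engineered_cys: offset {off} outside domain {lab}")

    def domain(self, label: str) -> DomainBlueprint:
        for d in self.domains:
            if d.label == label:
                return d
        raise SpecError(f"unknown domain label {label!r}")

    def domain_intervals(self) -> dict[str, tuple[int, int]]:
        return {d.label: (d.residue_number_start, d.residue_number_end)
                for d in self.domains}


def default_spec(order: int = 3, noise_sigma: float = 0.0, seed: int = 0,
                 engineered_cys: list[tuple[str, int]] | None = None) -> AssemblySpec:
    """The study conditions emulated by default: a flat C3 triangle of
    two-domain protomers whose centroid geometry matches a VirB8-like
    trimer — D1 centroids 30 A apart around the axis, the D2 of the same
    protomer 52 A away, and the interacting D2 of the neighbouring protomer
    at 23.8 A.
    """
    # D1 at radius 30/sqrt(3) from the axis; D2 placed so that the
    # same-protomer D1:D2 distance is 52 A and the cross-protomer D1:D2'
    # distance is 23.8 A (flat triangle, solved once from those targets).
    d1_center = np.array([17.320508, 0.0, 0.0])
    d2_center = np.array([-32.460236, 15.029222, 0.0])
    return AssemblySpec(
        order=order,
        domains=[
            DomainBlueprint("D1", residue_count=40, center=d1_center,
                            radius=11.0, residue_number_start=92),
            DomainBlueprint("D2", residue_count=36, center=d2_center,
                            radius=10.0, residue_number_start=228),
        ],
        linker_length=12,
        noise_sigma=noise_sigma,
        seed=seed,
        engineered_cys=engineered_cys,
    )


# ----------------------------------------------------------------------
# construction
# ----------------------------------------------------------------------

def _make_residue(name: str, number: int, chain_id: str, ca: np.ndarray,
                  serial_start: int, *, with_cb: bool = True) -> Residue:
    res = Residue(name, number)
    serial = serial_start
    names = ["N", "CA", "C", "O"] + (["CB"] if with_cb else [])
    for atom_name in names:
        offset = np.zeros(3) if atom_name == "CA" else _BACKBONE_OFFSETS[atom_name]
        res.atoms.append(AtomRecord(
            serial=serial, atom_name=atom_name, element=_ELEMENTS[atom_name],
            alt_loc="", residue_name=name, chain_id=chain_id,
            residue_number=number, insertion_code="", position=ca + offset))
        serial += 1
    return res


def make_protomer(spec: AssemblySpec) -> StructureModel:
    """Build the single-chain protomer of an :class:`AssemblySpec`.

    Each domain is a seeded cloud of 5-atom pseudo-residues whose CA
    positions fall inside a sphere of the blueprint radius, recentred so
    that the arithmetic mean of *all* the domain's atoms equals the
    blueprint center exactly.  Linker residues interpolate linearly between
    the edge CAs of consecutive domains.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng([spec.seed, 0])
    chain = Chain("A")
    serial = 1
    domain_edge_cas: list[tuple[np.ndarray, np.ndarray]] = []
    domain_residues: list[list[Residue]] = []

    for blueprint in spec.domains:
        directions = rng.normal(size=(blueprint.residue_count, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        radial = blueprint.radius * rng.random(blueprint.residue_count) ** (1.0 / 3.0)
        cas = blueprint.center + directions * radial[:, None]
        residues = []
        for i in range(blueprint.residue_count):
            res = _make_residue("ALA", blueprint.residue_number_start + i,
                                "A", cas[i], serial)
            serial += len(res.atoms)
            residues.append(res)
        # recentre: arithmetic mean of every atom == blueprint center exactly
        all_pos = np.vstack([a.position for r in residues for a in r.atoms])
        shift = blueprint.center - all_pos.mean(axis=0)
        for res in residues:
            for atom in res.atoms:
                atom.position = atom.position + shift
        domain_residues.append(residues)
        domain_edge_cas.append((residues[0].atom("CA").position,
                                residues[-1].atom("CA").position))

    # interleave domains and linkers in residue-number order
    for i, residues in enumerate(domain_residues):
        chain.residues.extend(residues)
        if spec.linker_length > 0 and i + 1 < len(domain_residues):
            start_ca = domain_edge_cas[i][1]
            end_ca = domain_edge_cas[i + 1][0]
            first_number = spec.domains[i].residue_number_end + 1
            for j in range(spec.linker_length):
                frac = (j + 1) / (spec.linker_length + 1)
                ca = start_ca + frac * (end_ca - start_ca)
                res = _make_residue("GLY", first_number + j, "A", ca, serial,
                                    with_cb=False)
                serial += len(res.atoms)
                chain.residues.append(res)

    return StructureModel(chains=[chain], id=f"protomer_seed{spec.seed}")


def _prime_rotation(spec: AssemblySpec) -> np.ndarray:
    """Rotation (about the spec axis) towards the protomer whose second
    domain sits closest to the first domain of the reference protomer —
    the interface the engineered cysteines are meant to trap.

    For a single-domain spec the +360/n rotation is returned.
    """
    step = 360.0 / spec.order
    if len(spec.domains) < 2:
        return rotation_about_axis(spec.axis_direction, step)
    c1 = spec.domains[0].center
    c2 = spec.domains[1].center
    best = None
    for sign in (1.0, -1.0):
        rot = rotation_about_axis(spec.axis_direction, sign * step)
        image = spec.axis_point + rot @ (c2 - spec.axis_point)
        dist = np.linalg.norm(c1 - image)
        if best is None or dist < best[0]:
            best = (dist, rot)
    return best[1]


def _place_engineered_cys(spec: AssemblySpec, protomer: StructureModel) -> None:
    """Turn the designated residues into CYS with SG (and CB) pseudo-atoms.

    For a facing pair, the SG atoms are placed so that after cyclic
    replication the two sulfurs across the interface sit exactly 2.05 A
    apart (and the CBs 4.2 A apart) when no noise is applied.  A single
    engineered residue gets an SG near its CB with no geometric pairing —
    the single-mutant control.
    """
    chain = protomer.chains[0]

    def _residue_for(label: str, offset: int) -> Residue:
        dom = spec.domain(label)
        res = chain.residue(dom.residue_number_start + offset)
        if res is None:
            raise SpecError(f"engineered residue {label}+{offset} not found")
        return res

    def _to_cys(res: Residue, cb: np.ndarray | None, sg: np.ndarray) -> None:
        res.name = "CYS"
        res.atoms = [a for a in res.atoms if a.atom_name not in ("CB", "SG")]
        ca = res.atom("CA").position
        if cb is None:
            cb = ca + _BACKBONE_OFFSETS["CB"]
            sg = cb + (cb - ca) / np.linalg.norm(cb - ca) * 1.8
        serial = max(a.serial for a in res.atoms)
        for name, pos in (("CB", cb), ("SG", sg)):
            serial += 1
            res.atoms.append(AtomRecord(
                serial=serial, atom_name=name, element=_ELEMENTS[name],
                alt_loc="", residue_name="CYS", chain_id=res.atoms[0].chain_id,
                residue_number=res.number, insertion_code="", position=pos))
        for atom in res.atoms:
            atom.residue_name = "CYS"

    pairs = spec.engineered_cys or []
    if len(pairs) == 1:
        _to_cys(_residue_for(*pairs[0]), None, None)
        return
    if len(pairs) != 2:
        return

    res_a = _residue_for(*pairs[0])
    res_b = _residue_for(*pairs[1])
    rot = _prime_rotation(spec)
    origin = spec.axis_point

    def fwd(x):
        return origin + rot @ (x - origin)

    def back(x):
        return origin + rot.T @ (x - origin)

    p_a = res_a.atom("CA").position
    p_b_image = fwd(res_b.atom("CA").position)
    midpoint = 0.5 * (p_a + p_b_image)
    u = p_a - p_b_image
    u = u / np.linalg.norm(u)
    _to_cys(res_a,
            midpoint + 0.5 * ENGINEERED_CB_CB * u,
            midpoint + 0.5 * DISULFIDE_SG_SG * u)
    _to_cys(res_b,
            back(midpoint - 0.5 * ENGINEERED_CB_CB * u),
            back(midpoint - 0.5 * DISULFIDE_SG_SG * u))


def make_cn_assembly(spec: AssemblySpec) -> StructureModel:
    """Protomer replicated into a Cn assembly, with optional post-replication
    Gaussian coordinate noise (which deliberately breaks exact symmetry) and
    optional engineered cysteines across the tightest cross-protomer
    interface."""
    protomer = make_protomer(spec)
    if spec.engineered_cys:
        _place_engineered_cys(spec, protomer)
    assembly = build_cyclic_assembly(protomer, spec.axis_point,
                                     spec.axis_direction, spec.order)
    assembly.id = f"cn{spec.order}_seed{spec.seed}"
    if spec.noise_sigma > 0:
        rng = np.random.default_rng([spec.seed, 1])
        for atom in assembly.iter_atoms():
            atom.position = atom.position + rng.normal(
                scale=spec.noise_sigma, size=3)
    return assembly


# ----------------------------------------------------------------------
# closed-form ground truth
# ----------------------------------------------------------------------

def expected_center_distances(spec: AssemblySpec) -> dict[str, float]:
    """Closed-form symmetry-class distances from the blueprint centers.

    Labels follow the prime convention: a prime per step to the next
    protomer around the axis, oriented so that the first cross-domain
    prime class is the closer of the two (the interacting interface).
    """
    from .geometry import canonical_class_label  # shared label convention

    n = spec.order
    step_rots = [rotation_about_axis(spec.axis_direction, 360.0 * k / n)
                 for k in range(n)]
    origin = spec.axis_point

    def center_of(label: str, pos: int) -> np.ndarray:
        c = spec.domain(label).center
        return origin + step_rots[pos] @ (c - origin)

    labels = [d.label for d in spec.domains]
    raw: dict[tuple[str, str, int], list[float]] = {}
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            for ka in range(n):
                for kb in range(n):
                    if (la, ka) >= (lb, kb):
                        continue
                    d = float(np.linalg.norm(center_of(la, ka) - center_of(lb, kb)))
                    if la == lb:
                        key = (la, lb, min((kb - ka) % n, (ka - kb) % n))
                    elif la < lb:
                        key = (la, lb, (kb - ka) % n)
                    else:
                        key = (lb, la, (ka - kb) % n)
                    raw.setdefault(key, []).append(d)

    # orient primes so the first cross-label prime class is the closer one
    flip = False
    cross = sorted({(a, b) for a, b, _ in raw if a != b})
    if cross and n > 2:
        a, b = cross[0]
        d1 = np.mean(raw.get((a, b, 1), [np.inf]))
        d2 = np.mean(raw.get((a, b, n - 1), [np.inf]))
        flip = d2 < d1
    out: dict[str, float] = {}
    for (a, b, off), values in raw.items():
        if a != b and flip:
            off = (n - off) % n
        out[canonical_class_label(a, b, off)] = float(np.mean(values))
    return out


def ground_truth(spec: AssemblySpec) -> dict:
    """Machine-readable sidecar of every quantity the tests assert:
    true centroids per chain and domain, exact class distances, and the
    engineered cysteine geometry."""
    n = spec.order
    chain_ids = [chr(ord("A") + k) for k in range(n)]
    step_rots = [rotation_about_axis(spec.axis_direction, 360.0 * k / n)
                 for k in range(n)]
    origin = spec.axis_point
    centers = {
        chain_ids[k]: {
            d.label: (origin + step_rots[k] @ (d.center - origin)).tolist()
            for d in spec.domains}
        for k in range(n)}
    truth = {
        "order": n,
        "seed": spec.seed,
        "noise_sigma": spec.noise_sigma,
        "axis_point": spec.axis_point.tolist(),
        "axis_direction": spec.axis_direction.tolist(),
        "domain_intervals": {lab: list(iv)
                             for lab, iv in spec.domain_intervals().items()},
        "true_centers": centers,
        "class_distances": expected_center_distances(spec),
    }
    if spec.engineered_cys and len(spec.engineered_cys) == 2:
        truth["engineered_cys"] = {
            "residues": [[lab, spec.domain(lab).residue_number_start + off]
                         for lab, off in spec.engineered_cys],
            "sg_sg_distance": DISULFIDE_SG_SG,
            "cb_cb_distance": ENGINEERED_CB_CB,
            "n_bridges": n if spec.noise_sigma == 0 else None,
        }
    return truth
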