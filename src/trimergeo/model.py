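"""Hierarchical atom container used throughout the package.

The container is deliberately small: chains -> residues -> atoms, plus the
crystallographic metadata (cell, space group, symmetry operators) needed to
expand a deposited monomer into the full cyclic assembly.  Coordinates are
orthogonal Angstroms.  Unmodelled residues are simply absent: author
numbering is preserved and never re-indexed, so gaps in the deposited model
(disordered loops, missing termini) survive every selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .errors import SelectionError

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

_STANDARD_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to their parent amino acid
    "MSE": "M", "SEC": "C",
}


def three_to_one(residue_name: str) -> str:
    """Map a 3-letter residue name to one-letter code ('X' if unknown)."""
    return _STANDARD_AA3TO1.get(residue_name.upper(), "X")


@dataclass
class AtomRecord:
    """One atom, PDB-style fields, orthogonal coordinates in Angstroms."""

    serial: int
    atom_name: str
    element: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_water(self) -> bool:
        return self.residue_name.upper() in WATER_NAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "AtomRecord":
        return replace(self, position=self.position.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AtomRecord):
            return NotImplemented
        return (
            self.serial == other.serial
            and self.atom_name == other.atom_name
            and self.element == other.element
            and self.alt_loc == other.alt_loc
            and self.residue_name == other.residue_name
            and self.chain_id == other.chain_id
            and self.residue_number == other.residue_number
            and self.insertion_code == other.insertion_code
            and bool(np.array_equal(self.position, other.position))
            and self.occupancy == other.occupancy
            and self.b_factor == other.b_factor
            and self.is_hetero == other.is_hetero
        )


@dataclass
class Residue:
    name: str
    number: int
    insertion_code: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.name.upper() in WATER_NAMES

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    def copy(self) -> "Residue":
        return Residue(self.name, self.number, self.insertion_code,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        return None

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])


@dataclass
class SymmetryOperator:
    """Rigid motion in the orthogonal frame: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3, translation a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation determinant must be +1")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=1e-9)
                and np.allclose(self.translation, 0.0, atol=1e-9))


@dataclass
class StructureModel:
    """Chains of residues of atoms, with optional crystal metadata."""

    chains: list[Chain] = field(default_factory=list)
    cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None
    symmetry_operators: list[SymmetryOperator] = field(default_factory=list)
    id: str = ""

    # -- iteration -----------------------------------------------------
    def iter_atoms(self, *, heavy_only: bool = False,
                   exclude_water: bool = False) -> Iterator[AtomRecord]:
        for chain in self.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    if heavy_only and atom.is_hydrogen:
                        continue
                    if exclude_water and atom.is_water:
                        continue
                    yield atom

    def atoms(self, **kw) -> list[AtomRecord]:
        return list(self.iter_atoms(**kw))

    def coords(self, *, heavy_only: bool = True,
               exclude_water: bool = True) -> np.ndarray:
        """(N, 3) coordinate array; by default heavy, non-water atoms only."""
        pts = [a.position for a in
               self.iter_atoms(heavy_only=heavy_only, exclude_water=exclude_water)]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    # -- lookup --------------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise SelectionError(
            f"chain {chain_id!r} not found (available: {self.chain_ids})")

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    # -- transformation ------------------------------------------------
    def copy(self) -> "StructureModel":
        return StructureModel(
            chains=[c.copy() for c in self.chains],
            cell=self.cell,
            space_group=self.space_group,
            symmetry_operators=list(self.symmetry_operators),
            id=self.id,
        )

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "StructureModel":
        """Return a rigidly moved copy: x -> R x + t for every atom."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = self.copy()
        for atom in out.iter_atoms():
            atom.position = rotation @ atom.position + translation
        return out

    def map_positions(self, fn: Callable[[np.ndarray], np.ndarray]) -> None:
        """Apply ``fn`` to every atom position in place."""
        for atom in self.iter_atoms():
            atom.position = np.asarray(fn(atom.position), dtype=float)

    def ca_coords(self, chain_id: str | None = None) -> np.ndarray:
        chains = [self.chain(chain_id)] if chain_id else self.chains
        pts = [r.atom("CA").position
               for c in chains for r in c.residues
               if not r.is_water and r.atom("CA") is not None]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureModel):
            return NotImplemented
        if self.id != other.id or self.space_group != other.space_group:
            return False
        if (self.cell is None) != (other.cell is None):
            return False
        if self.cell is not None and not np.allclose(self.cell, other.cell,
                                                     rtol=0, atol=0):
            return False
        if len(self.chains) != len(other.chains):
            return False
        for ca, cb in zip(self.chains, other.chains):
            if ca.id != cb.id or len(ca.residues) != len(cb.residues):
                return False
            for ra, rb in zip(ca.residues, cb.residues):
                if (ra.name, ra.number, ra.insertion_code) != \
                        (rb.name, rb.number, rb.insertion_code):
                    return False
                if ra.atoms != rb.atoms:
                    return False
        return True


def merge_models(parts: Sequence[StructureModel], *, id: str = "",
                 relabel: bool = True) -> StructureModel:
    """Concatenate models into one, relabelling chains A, B, C, ... and
    renumbering atom serials so they never collide."""
    out = StructureModel(id=id)
    serial = 1
    labels = _chain_label_stream()
    for part in parts:
        for chain in part.chains:
            new_chain = chain.copy()
            if relabel:
                new_chain.id = next(labels)
            for res in new_chain.residues:
                for atom in res.atoms:
                    atom.serial = serial
                    atom.chain_id = new_chain.id
                    serial += 1
            out.chains.append(new_chain)
    return out


def _chain_label_stream() -> Iterator[str]:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for ch in alphabet:
        yield ch
    for a in alphabet:
        for b in alphabet:
            yield a + b


def build_model(residue_specs: Iterable[tuple[str, int, list[tuple[str, str, np.ndarray]]]],
                chain_id: str = "A", *, id: str = "") -> StructureModel:
    """Convenience constructor for tests and fixtures.

    ``residue_specs`` yields (residue_name, residue_number,
    [(atom_name, element, xyz), ...]).
    """
    chain = Chain(chain_id)
    serial = 1
    for res_name, res_num, atom_specs in residue_specs:
        res = Residue(res_name, res_num)
        for atom_name, element, xyz in atom_specs:
            res.atoms.append(AtomRecord(
                serial=serial, atom_name=atom_name, element=element,
                alt_loc="", residue_name=res_name, chain_id=chain_id,
                residue_number=res_num, insertion_code="",
                position=np.asarray(xyz, dtype=float)))
            serial += 1
        chain.residues.append(res)
    return StructureModel(chains=[chain], id=id)
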