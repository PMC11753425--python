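"""Structure input/output, selection, symmetry expansion and mass utilities.

Parsing of PDB and mmCIF files is delegated to gemmi; the parsed hierarchy
is converted into the package's own :class:`~trimergeo.model.StructureModel`
with a deterministic alternate-location policy (highest occupancy wins, ties
broken by file order) so that every downstream geometry operation sees
exactly one position per atom.

Writing supports fixed-column PDB (for interoperability) and a JSON dump
that round-trips a model field-for-field (used for fixtures and reports).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (CapabilityError, ConfigurationError, ParseError,
                     SelectionError, ValidationError)
from .model import (AtomRecord, Chain, Residue, StructureModel,
                    SymmetryOperator, merge_models, three_to_one)

logger = logging.getLogger(__name__)

__all__ = [
    "read_structure", "write_structure", "select", "build_cyclic_assembly",
    "expand_crystal_symmetry", "extract_sequence", "molecular_weight",
    "rotation_about_axis", "axis_angle_of_rotation",
]

# Average (not monoisotopic) residue masses in Da, i.e. amino acid minus
# water; one water per chain is added back on assembly.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153


# ----------------------------------------------------------------------
# reading
# ----------------------------------------------------------------------

def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a structure from PDB, mmCIF or this package's JSON dump.

    Parameters
    ----------
    path : file path
    format : {"auto", "pdb", "mmcif", "json"}
        "auto" chooses by extension (.pdb/.ent -> pdb, .cif/.mmcif -> mmcif,
        .json -> json).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    fmt = format.lower()
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in (".pdb", ".ent"):
            fmt = "pdb"
        elif suffix in (".cif", ".mmcif"):
            fmt = "mmcif"
        elif suffix == ".json":
            fmt = "json"
        else:
            raise ConfigurationError(
                f"cannot infer format from extension {suffix!r}; "
                "pass format='pdb'|'mmcif'|'json'")
    if fmt == "json":
        return _model_from_dict(json.loads(path.read_text()))
    if fmt not in ("pdb", "mmcif"):
        raise ConfigurationError(f"unknown format {format!r}")

    import gemmi
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    return _from_gemmi(st, model_id=path.stem)


def _from_gemmi(st, model_id: str) -> StructureModel:
    import gemmi

    model = StructureModel(id=model_id)
    if st.cell and st.cell.a > 1.0:  # gemmi uses a dummy 1 A cell when absent
        model.cell = (st.cell.a, st.cell.b, st.cell.c,
                      st.cell.alpha, st.cell.beta, st.cell.gamma)
    hm = st.spacegroup_hm or None
    model.space_group = hm
    if model.cell is not None and hm:
        sg = gemmi.find_spacegroup_by_name(hm)
        if sg is not None:
            model.symmetry_operators = _orthogonal_operators(sg, st.cell)

    if len(st) == 0:
        raise ParseError(f"{model_id}: no models in file")
    gm = st[0]
    for gchain in gm:
        chain = Chain(gchain.name)
        for gres in gchain:
            icode = gres.seqid.icode.strip()
            res = Residue(gres.name, gres.seqid.num, icode)
            for atom in _dedupe_altlocs(gres):
                alt = atom.altloc if atom.altloc != "\x00" else ""
                res.atoms.append(AtomRecord(
                    serial=atom.serial,
                    atom_name=atom.name,
                    element=atom.element.name.upper(),
                    alt_loc=alt,
                    residue_name=gres.name,
                    chain_id=gchain.name,
                    residue_number=gres.seqid.num,
                    insertion_code=icode,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    b_factor=atom.b_iso,
                    is_hetero=(gres.het_flag == "H"),
                ))
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            model.chains.append(chain)
    return model


def _dedupe_altlocs(gres):
    """Keep one conformer per atom name: highest occupancy, ties -> first."""
    best: dict[str, object] = {}
    order: list[str] = []
    for atom in gres:
        name = atom.name
        if name not in best:
            best[name] = atom
            order.append(name)
        elif atom.occ > best[name].occ:
            best[name] = atom
    return [best[name] for name in order]


def _orthogonal_operators(sg, cell) -> list[SymmetryOperator]:
    """Convert fractional space-group operators to the orthogonal frame.

    Only proper rotations are returned (protein crystals belong to Sohncke
    groups, so nothing is lost for the structures this package handles).
    """
    orth = np.array(cell.orth.mat.tolist())
    orth_inv = np.linalg.inv(orth)
    ops: list[SymmetryOperator] = []
    for op in sg.operations():
        rot_frac = np.array(op.rot, dtype=float) / op.DEN
        tran_frac = np.array(op.tran, dtype=float) / op.DEN
        rot = orth @ rot_frac @ orth_inv
        if np.linalg.det(rot) < 0:
            continue
        ops.append(SymmetryOperator(rotation=rot, translation=orth @ tran_frac))
    return ops


# ----------------------------------------------------------------------
# writing
# ----------------------------------------------------------------------

def write_structure(model: StructureModel, path: str | Path,
                    format: str = "auto") -> None:
    """Write a model as fixed-column PDB or as a JSON dump."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "json" if path.suffix.lower() == ".json" else "pdb"
    if fmt == "json":
        path.write_text(json.dumps(_model_to_dict(model), indent=1))
    elif fmt == "pdb":
        path.write_text(_to_pdb_string(model))
    else:
        raise ConfigurationError(f"unknown output format {format!r}")


def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: 1-2 letter elements start in column 14 unless the
    # name is 4 characters long.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _to_pdb_string(model: StructureModel) -> str:
    lines: list[str] = []
    if model.cell is not None:
        a, b, c, al, be, ga = model.cell
        sg = (model.space_group or "P 1")[:11]
        lines.append(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}"
                     f"{al:7.2f}{be:7.2f}{ga:7.2f} {sg:<11s}   1")
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                record = "HETATM" if atom.is_hetero else "ATOM  "
                name = _format_atom_name(atom.atom_name, atom.element)
                alt = atom.alt_loc or " "
                icode = atom.insertion_code or " "
                x, y, z = atom.position
                lines.append(
                    f"{record}{atom.serial:5d} {name}{alt}"
                    f"{atom.residue_name:>3s} {chain.id[:1]}"
                    f"{atom.residue_number:4d}{icode}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                    f"          {atom.element:>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _model_to_dict(model: StructureModel) -> dict:
    return {
        "id": model.id,
        "cell": list(model.cell) if model.cell is not None else None,
        "space_group": model.space_group,
        "symmetry_operators": [
            {"rotation": op.rotation.tolist(),
             "translation": op.translation.tolist()}
            for op in model.symmetry_operators],
        "chains": [
            {"id": c.id,
             "residues": [
                 {"name": r.name, "number": r.number,
                  "insertion_code": r.insertion_code,
                  "atoms": [
                      {"serial": a.serial, "atom_name": a.atom_name,
                       "element": a.element, "alt_loc": a.alt_loc,
                       "position": a.position.tolist(),
                       "occupancy": a.occupancy, "b_factor": a.b_factor,
                       "is_hetero": a.is_hetero}
                      for a in r.atoms]}
                 for r in c.residues]}
            for c in model.chains],
    }


def _model_from_dict(data: dict) -> StructureModel:
    model = StructureModel(
        id=data.get("id", ""),
        cell=tuple(data["cell"]) if data.get("cell") else None,
        space_group=data.get("space_group"),
        symmetry_operators=[
            SymmetryOperator(np.array(op["rotation"]),
                             np.array(op["translation"]))
            for op in data.get("symmetry_operators", [])],
    )
    for cdata in data.get("chains", []):
        chain = Chain(cdata["id"])
        for rdata in cdata["residues"]:
            res = Residue(rdata["name"], rdata["number"],
                          rdata.get("insertion_code", ""))
            for adata in rdata["atoms"]:
                res.atoms.append(AtomRecord(
                    serial=adata["serial"], atom_name=adata["atom_name"],
                    element=adata["element"], alt_loc=adata.get("alt_loc", ""),
                    residue_name=res.name, chain_id=chain.id,
                    residue_number=res.number,
                    insertion_code=res.insertion_code,
                    position=np.array(adata["position"]),
                    occupancy=adata.get("occupancy", 1.0),
                    b_factor=adata.get("b_factor", 0.0),
                    is_hetero=adata.get("is_hetero", False)))
            chain.residues.append(res)
        model.chains.append(chain)
    return model


# ----------------------------------------------------------------------
# selection
# ----------------------------------------------------------------------

def select(model: StructureModel, chain_id: str,
           intervals: Sequence[tuple[int, int]]) -> StructureModel:
    """Select residues of one chain whose author number falls in any of the
    inclusive ``intervals``.  Unmodelled residues are silently absent; an
    empty selection is allowed."""
    for start, end in intervals:
        if start > end:
            raise ConfigurationError(
                f"malformed interval [{start}, {end}]: start > end")
    chain = model.chain(chain_id)  # raises SelectionError if missing
    new_chain = Chain(chain.id)
    for res in chain.residues:
        if any(start <= res.number <= end for start, end in intervals):
            new_chain.residues.append(res.copy())
    out = StructureModel(chains=[new_chain], cell=model.cell,
                         space_group=model.space_group,
                         symmetry_operators=list(model.symmetry_operators),
                         id=model.id)
    return out


# ----------------------------------------------------------------------
# symmetry
# ----------------------------------------------------------------------

def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ConfigurationError("axis direction must be non-zero")
    return Rotation.from_rotvec(axis / norm * math.radians(angle_deg)).as_matrix()


def axis_angle_of_rotation(rotation: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit rotation axis and angle (degrees, in [0, 180]) of a proper
    rotation matrix; the axis is the eigenvector for eigenvalue 1."""
    rotvec = Rotation.from_matrix(np.asarray(rotation, dtype=float)).as_rotvec()
    angle = np.linalg.norm(rotvec)
    if angle < 1e-12:
        return np.array([0.0, 0.0, 1.0]), 0.0
    return rotvec / angle, math.degrees(angle)


def build_cyclic_assembly(monomer: StructureModel, axis_point: np.ndarray,
                          axis_direction: np.ndarray,
                          order: int) -> StructureModel:
    """Replicate a monomer about a cyclic axis into a Cn assembly.

    Copy ``k`` is the monomer rotated by ``360 k / order`` degrees about the
    axis through ``axis_point`` along ``axis_direction``; chains are
    relabelled A, B, C, ... and atom serials renumbered.
    """
    if not isinstance(order, int) or order < 2:
        raise ConfigurationError(f"cyclic order must be an integer >= 2, got {order}")
    if monomer.n_atoms() == 0:
        raise ConfigurationError("monomer is empty")
    axis_point = np.asarray(axis_point, dtype=float)
    copies = []
    for k in range(order):
        rot = rotation_about_axis(axis_direction, 360.0 * k / order)
        tran = axis_point - rot @ axis_point
        copies.append(monomer.transformed(rot, tran))
    out = merge_models(copies, id=f"{monomer.id}_c{order}" if monomer.id else f"c{order}")
    out.cell = monomer.cell
    out.space_group = monomer.space_group
    return out


def expand_crystal_symmetry(model: StructureModel,
                            operator_indices: Sequence[int]) -> StructureModel:
    """Apply the chosen crystallographic operators (already expressed in the
    orthogonal frame) and merge the copies into one model with distinct
    chain ids.  Applying only the identity returns the model unchanged."""
    if model.cell is None or not model.symmetry_operators:
        raise CapabilityError(
            "model carries no cell/symmetry operators; cannot expand")
    ops = []
    for idx in operator_indices:
        if idx < 0 or idx >= len(model.symmetry_operators):
            raise ConfigurationError(
                f"operator index {idx} out of range "
                f"(0..{len(model.symmetry_operators) - 1})")
        ops.append(model.symmetry_operators[idx])
    if len(ops) == 1 and ops[0].is_identity:
        return model.copy()
    copies = [model.copy() if op.is_identity
              else model.transformed(op.rotation, op.translation)
              for op in ops]
    out = merge_models(copies, id=f"{model.id}_sym" if model.id else "sym")
    out.cell = model.cell
    out.space_group = model.space_group
    return out


# ----------------------------------------------------------------------
# sequence & mass
# ----------------------------------------------------------------------

def extract_sequence(model: StructureModel, chain_id: str) -> str:
    """One-letter sequence of the modelled polymer residues of a chain.

    A residue counts as polymer when it is not water and carries a CA atom.
    MSE maps to M and SEC to C; other non-standard residues map to X.
    Gaps (unmodelled residues) are not padded.
    """
    chain = model.chain(chain_id)
    letters = []
    for res in chain.residues:
        if res.is_water or res.atom("CA") is None:
            continue
        letter = three_to_one(res.name)
        if letter == "X":
            logger.warning("non-standard residue %s %s%d mapped to X",
                           res.name, chain_id, res.number)
        letters.append(letter)
    return "".join(letters)


def molecular_weight(sequence: str, multiplicity: int = 1) -> float:
    """Average molecular mass in Da of ``multiplicity`` copies of a chain.

    Sum of average residue masses plus one water per chain.  'X' residues
    (unknown) are excluded with a warning; any other unknown letter is an
    error.
    """
    if not isinstance(multiplicity, int) or multiplicity < 1:
        raise ValidationError(f"multiplicity must be an integer >= 1, got {multiplicity}")
    if not sequence:
        raise ValidationError("empty sequence")
    mass = WATER_MASS
    for letter in sequence.upper():
        if letter == "X":
            logger.warning("unknown residue 'X' excluded from mass")
            continue
        try:
            mass += AVERAGE_RESIDUE_MASS[letter]
        except KeyError:
            raise ValidationError(f"unknown amino-acid letter {letter!r}") from None
    return mass * multiplicity
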