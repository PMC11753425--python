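"""End-to-end orchestration: load/build assemblies, geometry fingerprints,
structure comparisons, interface reports and cross-link design/validation.

A run is described by a single :class:`RunConfig` (usually read from a
YAML/JSON file).  Stages execute in a fixed order and any failure aborts
with a stage-labelled error; outputs are written atomically and a run with
identical config and inputs produces a byte-identical JSON report apart
from its timestamp.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import __version__ as _version
from .crosslink import (CB_WINDOW, crosslink_consistency, scan_disulfide_sites,
                        validate_disulfides)
from .errors import ConfigurationError, TrimerGeoError
from .geometry import (DomainDefinition, classify_distance_classes,
                       definitions_for_assembly, domain_center)
from .interfaces import CONTACT_CUTOFF, SasaParams, interface_report
from .model import StructureModel
from .structure_io import (build_cyclic_assembly, expand_crystal_symmetry,
                           read_structure, write_structure)
from .superpose import compare_models
from .synthetic import (AssemblySpec, DomainBlueprint, default_spec,
                        ground_truth, make_cn_assembly)

__all__ = ["RunConfig", "StructureInput", "AnalysisReport", "run_pipeline",
           "make_fixtures", "load_config"]


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

@dataclass
class StructureInput:
    """One structure entering the pipeline: either a file plus an assembly
    mode, or a synthetic specification."""

    id: str
    path: Optional[str] = None
    synthetic: Optional[dict] = None           # AssemblySpec field overrides
    domains: dict[str, tuple[int, int]] = dc_field(default_factory=dict)
    assembly_mode: str = "asymmetric_unit"     # | crystal_symmetry | explicit_axis
    operator_indices: Optional[list[int]] = None
    axis_point: Optional[list[float]] = None
    axis_direction: Optional[list[float]] = None


@dataclass
class RunConfig:
    structures: list[StructureInput]
    order: int = 3
    atom_mode: str = "all_heavy"
    contact_cutoff: float = CONTACT_CUTOFF
    cb_window: tuple[float, float] = CB_WINDOW
    sasa_probe_radius: float = 1.4
    sasa_sphere_points: int = 960
    seed: int = 0
    output_dir: Optional[str] = None
    compare: bool = True

    def validate(self) -> None:
        if self.order < 2:
            raise ConfigurationError(f"order must be >= 2, got {self.order}")
        if not self.structures:
            raise ConfigurationError("no structures configured")
        for st in self.structures:
            if (st.path is None) == (st.synthetic is None):
                raise ConfigurationError(
                    f"structure {st.id!r}: exactly one of path/synthetic required")
            if st.path is not None and not Path(st.path).exists():
                raise ConfigurationError(
                    f"structure {st.id!r}: file not found: {st.path}")
            if not st.domains and st.synthetic is None:
                raise ConfigurationError(
                    f"structure {st.id!r}: domain definitions required")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML or JSON file."""
    raw = yaml.safe_load(Path(path).read_text())
    structures = [StructureInput(
        id=s["id"],
        path=s.get("path"),
        synthetic=s.get("synthetic"),
        domains={k: tuple(v) for k, v in s.get("domains", {}).items()},
        assembly_mode=s.get("assembly_mode", "asymmetric_unit"),
        operator_indices=s.get("operator_indices"),
        axis_point=s.get("axis_point"),
        axis_direction=s.get("axis_direction"),
    ) for s in raw.get("structures", [])]
    kwargs = {k: raw[k] for k in ("order", "atom_mode", "contact_cutoff",
                                  "seed", "output_dir", "compare")
              if k in raw}
    if "cb_window" in raw:
        kwargs["cb_window"] = tuple(raw["cb_window"])
    sasa_cfg = raw.get("sasa", {})
    if "probe_radius" in sasa_cfg:
        kwargs["sasa_probe_radius"] = sasa_cfg["probe_radius"]
    if "sphere_points" in sasa_cfg:
        kwargs["sasa_sphere_points"] = sasa_cfg["sphere_points"]
    return RunConfig(structures=structures, **kwargs)


# ----------------------------------------------------------------------
# report schema (pydantic -> published JSON schema)
# ----------------------------------------------------------------------

class DistanceClassRow(BaseModel):
    structure: str
    class_label: str
    members: int
    mean_A: float
    rmsd_A: float


class ComparisonRow(BaseModel):
    structure_a: str
    structure_b: str
    mode: str
    tm_mean: float
    rmsd_mean: float
    n_pairs_mean: float
    n_comparisons: int


class InterfaceRow(BaseModel):
    structure: str
    pair_label: str
    n_equivalent: int
    interface_area_A2: float
    buried_area_total_A2: float
    n_contacts: float
    n_hbonds: float


class CrosslinkCandidateRow(BaseModel):
    structure: str
    residue_a: list
    residue_b: list
    cb_cb_A: float
    ca_ca_A: float
    rank: int


class DisulfideRow(BaseModel):
    structure: str
    cys_a: list
    cys_b: list
    sg_sg_A: float
    interchain: bool


class Provenance(BaseModel):
    package_version: str
    seed: int
    order: int
    atom_mode: str
    contact_cutoff: float
    cb_window: list[float]
    sasa_probe_radius: float
    sasa_sphere_points: int
    inputs: list[str]
    timestamp: str = Field(description="UTC, excluded from determinism checks")


class AnalysisReport(BaseModel):
    """Machine-readable result of a full pipeline run."""

    distance_classes: list[DistanceClassRow]
    comparisons: list[ComparisonRow]
    interfaces: list[InterfaceRow]
    crosslink_candidates: list[CrosslinkCandidateRow]
    disulfides: list[DisulfideRow]
    crosslink_consistency: dict[str, Any]
    provenance: Provenance

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=1, sort_keys=True)


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------

def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except TrimerGeoError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
        return wrapper
    return deco


def _spec_from_dict(overrides: dict, order: int, seed: int) -> AssemblySpec:
    if "domains" in overrides:
        domains = [DomainBlueprint(**d) for d in overrides["domains"]]
        spec = AssemblySpec(
            order=overrides.get("order", order),
            axis_point=np.asarray(overrides.get("axis_point", [0, 0, 0]), float),
            axis_direction=np.asarray(overrides.get("axis_direction", [0, 0, 1]), float),
            domains=domains,
            linker_length=overrides.get("linker_length", 0),
            noise_sigma=overrides.get("noise_sigma", 0.0),
            seed=overrides.get("seed", seed),
            engineered_cys=[tuple(p) for p in overrides["engineered_cys"]]
            if overrides.get("engineered_cys") else None,
        )
        return spec
    return default_spec(
        order=overrides.get("order", order),
        noise_sigma=overrides.get("noise_sigma", 0.0),
        seed=overrides.get("seed", seed),
        engineered_cys=[tuple(p) for p in overrides["engineered_cys"]]
        if overrides.get("engineered_cys") else None,
    )


@_stage("load")
def _load_structure(st: StructureInput, config: RunConfig,
                    ) -> tuple[StructureModel, dict[str, tuple[int, int]]]:
    if st.synthetic is not None:
        spec = _spec_from_dict(st.synthetic, config.order, config.seed)
        model = make_cn_assembly(spec)
        model.id = st.id
        domains = st.domains or spec.domain_intervals()
        return model, domains
    model = read_structure(st.path)
    model.id = st.id
    if st.assembly_mode == "asymmetric_unit":
        pass
    elif st.assembly_mode == "crystal_symmetry":
        indices = st.operator_indices
        if indices is None:
            raise ConfigurationError(
                f"structure {st.id!r}: crystal_symmetry needs operator_indices")
        model = expand_crystal_symmetry(model, indices)
    elif st.assembly_mode == "explicit_axis":
        if st.axis_point is None or st.axis_direction is None:
            raise ConfigurationError(
                f"structure {st.id!r}: explicit_axis needs axis_point/axis_direction")
        model = build_cyclic_assembly(model, np.asarray(st.axis_point, float),
                                      np.asarray(st.axis_direction, float),
                                      config.order)
    else:
        raise ConfigurationError(
            f"structure {st.id!r}: unknown assembly_mode {st.assembly_mode!r}")
    return model, st.domains


def _prime_partner(assembly: StructureModel,
                   domains: dict[str, tuple[int, int]]) -> dict[str, str]:
    """chain -> the neighbouring chain whose second domain sits closest to
    this chain's first domain (the interacting interface)."""
    labels = sorted(domains)
    first, second = labels[0], (labels[1] if len(labels) > 1 else labels[0])
    defs = definitions_for_assembly(domains, assembly.chain_ids)
    centers = {(d.label, d.chain_id): domain_center(assembly, d).center
               for d in defs}
    partners = {}
    for cid in assembly.chain_ids:
        others = [c for c in assembly.chain_ids if c != cid]
        partners[cid] = min(
            others, key=lambda c: float(np.linalg.norm(
                centers[(first, cid)] - centers[(second, c)])))
    return partners


@_stage("interfaces")
def _interface_rows(name: str, assembly: StructureModel,
                    domains: dict[str, tuple[int, int]],
                    config: RunConfig) -> list[InterfaceRow]:
    params = SasaParams(probe_radius=config.sasa_probe_radius,
                        sphere_points=config.sasa_sphere_points)
    labels = sorted(domains)
    partners = _prime_partner(assembly, domains)
    rows = []
    pairings = [(labels[0], labels[0])]
    if len(labels) > 1:
        pairings.append((labels[0], labels[1]))
    for la, lb in pairings:
        reports = []
        for cid in assembly.chain_ids:
            other = partners[cid]
            reports.append(interface_report(
                assembly,
                DomainDefinition(la, cid, [domains[la]]),
                DomainDefinition(lb, other, [domains[lb]]),
                params, config.contact_cutoff))
        rows.append(InterfaceRow(
            structure=name,
            pair_label=f"{la}:{lb}′",
            n_equivalent=len(reports),
            interface_area_A2=float(np.mean([r.interface_area for r in reports])),
            buried_area_total_A2=float(np.mean([r.buried_area_total for r in reports])),
            n_contacts=float(np.mean([len(r.contacts) for r in reports])),
            n_hbonds=float(np.mean([r.hbond_count for r in reports])),
        ))
    return rows


@_stage("crosslink")
def _crosslink_rows(name: str, assembly: StructureModel,
                    domains: dict[str, tuple[int, int]], config: RunConfig,
                    ) -> tuple[list[CrosslinkCandidateRow], list[DisulfideRow], dict]:
    labels = sorted(domains)
    cand_rows: list[CrosslinkCandidateRow] = []
    candidates = []
    if len(labels) > 1:
        partners = _prime_partner(assembly, domains)
        cid = assembly.chain_ids[0]
        candidates = scan_disulfide_sites(
            assembly,
            DomainDefinition(labels[0], cid, [domains[labels[0]]]),
            DomainDefinition(labels[1], partners[cid], [domains[labels[1]]]),
            config.cb_window)
        cand_rows = [CrosslinkCandidateRow(
            structure=name, residue_a=list(c.residue_a),
            residue_b=list(c.residue_b), cb_cb_A=c.cb_cb_distance,
            ca_ca_A=c.ca_ca_distance, rank=i + 1)
            for i, c in enumerate(candidates[:25])]
    bonds = validate_disulfides(assembly)
    bond_rows = [DisulfideRow(
        structure=name, cys_a=list(b.cys_a), cys_b=list(b.cys_b),
        sg_sg_A=b.sg_sg_distance, interchain=b.is_interchain)
        for b in bonds]
    consistency = crosslink_consistency(candidates, bonds, config.order)
    return cand_rows, bond_rows, consistency


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute all stages on the configured structures.

    Stage order: load/assemble -> distance classes -> model comparisons
    (between consecutive structure pairs) -> interface reports ->
    cross-link design and validation.
    """
    config.validate()
    loaded: list[tuple[str, StructureModel, dict]] = []
    for st in config.structures:
        model, domains = _load_structure(st, config)
        loaded.append((st.id, model, domains))

    distance_rows: list[DistanceClassRow] = []
    for name, model, domains in loaded:
        defs = definitions_for_assembly(domains, model.chain_ids)
        for summary in classify_distance_classes(model, defs, config.order,
                                                 config.atom_mode):
            distance_rows.append(DistanceClassRow(
                structure=name, class_label=summary.class_label,
                members=len(summary.members), mean_A=summary.mean,
                rmsd_A=summary.rmsd))

    comparison_rows: list[ComparisonRow] = []
    if config.compare and len(loaded) > 1:
        for (na, ma, da), (nb, mb, db) in zip(loaded, loaded[1:]):
            modes = sorted(da) + (["pair_same", "pair_prime"]
                                  if len(da) > 1 and len(db) > 1 else [])
            for mode in modes:
                row = compare_models(ma, mb, mode, da, db, config.order)
                comparison_rows.append(ComparisonRow(
                    structure_a=na, structure_b=nb, mode=mode,
                    tm_mean=row["tm_mean"], rmsd_mean=row["rmsd_mean"],
                    n_pairs_mean=row["n_pairs_mean"],
                    n_comparisons=row["n_comparisons"]))

    interface_rows: list[InterfaceRow] = []
    cand_rows: list[CrosslinkCandidateRow] = []
    bond_rows: list[DisulfideRow] = []
    consistency: dict[str, Any] = {}
    for name, model, domains in loaded:
        interface_rows.extend(_interface_rows(name, model, domains, config))
        cands, bonds, cons = _crosslink_rows(name, model, domains, config)
        cand_rows.extend(cands)
        bond_rows.extend(bonds)
        consistency[name] = cons

    report = AnalysisReport(
        distance_classes=distance_rows,
        comparisons=comparison_rows,
        interfaces=interface_rows,
        crosslink_candidates=cand_rows,
        disulfides=bond_rows,
        crosslink_consistency=consistency,
        provenance=Provenance(
            package_version=_version,
            seed=config.seed,
            order=config.order,
            atom_mode=config.atom_mode,
            contact_cutoff=config.contact_cutoff,
            cb_window=list(config.cb_window),
            sasa_probe_radius=config.sasa_probe_radius,
            sasa_sphere_points=config.sasa_sphere_points,
            inputs=[st.path or f"synthetic:{st.id}" for st in config.structures],
            timestamp=datetime.now(timezone.utc).isoformat(),
        ),
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _atomic_write(out / "report.json", report.to_json())
    return report


# ----------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------

def make_fixtures(spec_file: str | Path | None, out_dir: str | Path,
                  seed: int | None = None) -> tuple[Path, Path]:
    """Emit a synthetic assembly PDB plus its ground-truth JSON sidecar.

    ``spec_file`` is a YAML/JSON file of AssemblySpec fields (or None for
    the default study conditions).  The sidecar contains every quantity the
    test suite asserts: true centroids, exact class distances and the
    engineered cysteine geometry.
    """
    overrides = {}
    if spec_file is not None:
        overrides = yaml.safe_load(Path(spec_file).read_text()) or {}
    if seed is not None:
        overrides["seed"] = seed
    spec = _spec_from_dict(overrides, overrides.get("order", 3),
                           overrides.get("seed", 0))
    assembly = make_cn_assembly(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pdb_path = out / f"{assembly.id}.pdb"
    truth_path = out / f"{assembly.id}.truth.json"
    write_structure(assembly, pdb_path, format="pdb")
    _atomic_write(truth_path, json.dumps(ground_truth(spec), indent=1,
                                         sort_keys=True))
    return pdb_path, truth_path
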