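"""Shared fixtures: synthetic assemblies with closed-form ground truth."""

from pathlib import Path

import numpy as np
import pytest

from trimergeo import (default_spec, definitions_for_assembly,
                       make_cn_assembly, make_protomer)

#: directory where user-fetched deposited structures are expected
PDB_DIR = Path(__file__).resolve().parent.parent / "data" / "pdb"


def require_pdb(code: str) -> Path:
    """Path to a locally fetched deposited entry; fail with instructions
    when absent (these checks need structure files this repository cannot
    ship)."""
    path = PDB_DIR / f"{code}.pdb"
    if not path.exists():
        pytest.fail(
            f"deposited structure {code!r} not present at {path}; run "
            "`python scripts/fetch_pdb.py` on a machine with internet "
            "access to enable this check", pytrace=False)
    return path


@pytest.fixture(scope="session")
def exact_spec():
    return default_spec(seed=0)


@pytest.fixture(scope="session")
def exact_assembly(exact_spec):
    """Noise-free C3 assembly: every symmetry class has RMSD exactly 0."""
    return make_cn_assembly(exact_spec)


@pytest.fixture(scope="session")
def exact_defs(exact_spec, exact_assembly):
    return definitions_for_assembly(exact_spec.domain_intervals(),
                                    exact_assembly.chain_ids)


@pytest.fixture(scope="session")
def protomer(exact_spec):
    return make_protomer(exact_spec)


@pytest.fixture(scope="session")
def cys_spec():
    return default_spec(seed=0, engineered_cys=[("D1", 10), ("D2", 5)])


@pytest.fixture(scope="session")
def cys_assembly(cys_spec):
    """Exact C3 trimer with an engineered disulfide pair across each
    D1:D2' interface (Sg-Sg 2.05 A, Cb-Cb 4.2 A)."""
    return make_cn_assembly(cys_spec)


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation and a bounded translation."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    return rot, rng.uniform(-50, 50, size=3)
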