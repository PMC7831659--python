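import numpy as np
import pytest

from structmanip.fixtures import (FixtureParams, icosahedral_matrices,
                                  make_toy_capsomer,
                                  write_icosahedral_capsid_file)
from structmanip.pdbio import Atom, Unit


@pytest.fixture(scope="session")
def icosa():
    return icosahedral_matrices()


@pytest.fixture(scope="session")
def capsomer():
    return make_toy_capsomer(FixtureParams(seed=42))


@pytest.fixture(scope="session")
def capsid_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("fixtures") / "toy_capsid.pdb"
    write_icosahedral_capsid_file(path, FixtureParams(seed=42))
    return path


def make_random_unit(seed: int, n_atoms: int = 100, center=(0.0, 0.0, 0.0),
                     spread: float = 5.0, label: str = "rand") -> Unit:
    """A seeded blob of carbon atoms with masses assigned; test workhorse."""
    rng = np.random.default_rng(seed)
    pos = np.asarray(center, dtype=float) + rng.normal(0.0, spread, (n_atoms, 3))
    atoms = [Atom(serial=i + 1, name=f"C{i + 1}", altloc=" ", resname="ALA",
                  chain_id="A", resseq=i + 1, icode=" ",
                  position=pos[i], element="C", mass=12.011)
             for i in range(n_atoms)]
    return Unit(atoms, label=label)


@pytest.fixture
def random_unit():
    return make_random_unit
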