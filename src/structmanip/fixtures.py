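"""Synthetic test assemblies: toy capsomers, icosahedral BIOMT sets, helical
lattices, and charged dimers.

Everything here is deliberately *not* a realistic protein: units are compact
random-coil blobs with plausible element composition and mass, placed with
exact symmetry so that geometric invariants (equal capsomer radii, lattice
centroids on the cylinder axis) hold to machine precision.  All randomness
sits behind a single integer seed, so fixtures are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .pdbio import (Atom, BiomtMatrix, Unit, format_biomt_remarks,
                    standard_mass, write_structure)

__all__ = [
    "FixtureParams",
    "icosahedral_matrices",
    "make_toy_capsomer",
    "make_helical_assembly",
    "make_charged_dimer",
    "write_icosahedral_capsid_file",
]

#: generic direction (off every icosahedral symmetry axis) for the primary
#: capsomer center, so the 60 symmetry copies are all distinct
_GENERIC_DIRECTION = np.array([1.0, 0.7, 0.3])

_ELEMENTS = np.array(["C", "N", "O", "S"])
_ELEMENT_P = np.array([0.62, 0.17, 0.16, 0.05])


@dataclass
class FixtureParams:
    """Knobs for the synthetic generators.

    ``radius`` places the toy capsomer's mass center (so it equals the
    symmetric-shell R_M of the assembled toy capsid); the helical defaults
    emulate a 13-protofilament microtubule-like lattice (cylinder radius
    ~115 A, ~82 A axial repeat).
    """

    n_chains: int = 3
    atoms_per_chain: int = 50
    radius: float = 100.0
    seed: int = 42
    protofilaments: int = 13
    rings: int = 3
    cyl_radius: float = 115.0
    rise: float = 82.0
    twist: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_chains", "atoms_per_chain", "protofilaments", "rings"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def icosahedral_matrices() -> list[BiomtMatrix]:
    """The 60 proper rotations of the icosahedral group as BIOMT matrices.

    Translations are zero and indices run 1-60 with the identity first;
    the set is closed under composition (a finite rotation group).
    """
    mats = Rotation.create_group("I").as_matrix()
    # deterministic order: identity first, then lexicographic on entries
    keys = [tuple(np.round(m, 9).ravel()) for m in mats]
    order = sorted(range(len(mats)),
                   key=lambda i: (-np.trace(mats[i]), keys[i]))
    return [BiomtMatrix(index=k + 1, rotation=mats[i],
                        translation=np.zeros(3))
            for k, i in enumerate(order)]


def _blob_atoms(rng: np.random.Generator, n_chains: int, atoms_per_chain: int,
                spread: float = 2.5, chain_gap: float = 8.0,
                resname: str = "ALA") -> list[Atom]:
    atoms: list[Atom] = []
    serial = 1
    for c in range(n_chains):
        chain_id = chr(ord("A") + c)
        offset = np.array([0.0, chain_gap * (c - (n_chains - 1) / 2), 0.0])
        for j in range(atoms_per_chain):
            element = str(rng.choice(_ELEMENTS, p=_ELEMENT_P))
            atoms.append(Atom(
                serial=serial,
                name=f"{element}{j + 1}",
                altloc=" ",
                resname=resname,
                chain_id=chain_id,
                resseq=j + 1,
                icode=" ",
                position=offset + rng.normal(0.0, spread, 3),
                occupancy=1.0,
                bfactor=0.0,
                element=element,
                mass=standard_mass(element),
            ))
            serial += 1
    return atoms


def _recenter(unit: Unit, target: np.ndarray) -> Unit:
    masses = unit.masses
    com = masses @ unit.positions / masses.sum()
    return unit.with_positions(unit.positions - com + target)


def make_toy_capsomer(params: FixtureParams | None = None) -> Unit:
    """A compact random-coil blob standing in for one capsomer.

    Three chains by default, mirroring a capsomer's three quasi-equivalent
    protein subunits.  Its mass center sits exactly ``radius`` A from the
    origin along a generic (non-symmetry-axis) direction, so the 60
    icosahedral copies tile a shell of symmetric R_M = ``radius``.
    """
    params = params or FixtureParams()
    rng = np.random.default_rng(params.seed)
    unit = Unit(_blob_atoms(rng, params.n_chains, params.atoms_per_chain),
                label="toy_capsomer",
                provenance=[f"synthetic capsomer seed={params.seed}"])
    target = params.radius * _GENERIC_DIRECTION / np.linalg.norm(_GENERIC_DIRECTION)
    return _recenter(unit, target)


def make_helical_assembly(params: FixtureParams | None = None) -> list[Unit]:
    """Subunit copies on a cylindrical (microtubule-like) lattice, axis = z.

    ``protofilaments`` positions per ring at equal azimuth, ``rings`` rings
    spaced ``rise`` A apart, each ring twisted by ``twist`` degrees relative
    to the previous.  Every subunit's mass center lies exactly on the
    cylinder of radius ``cyl_radius``.
    """
    params = params or FixtureParams()
    rng = np.random.default_rng(params.seed)
    blob = Unit(_blob_atoms(rng, 1, params.atoms_per_chain),
                label="mt_subunit",
                provenance=[f"synthetic tubulin blob seed={params.seed}"])
    units: list[Unit] = []
    for r in range(params.rings):
        for p in range(params.protofilaments):
            angle = 2 * np.pi * p / params.protofilaments \
                + np.deg2rad(params.twist) * r
            center = np.array([params.cyl_radius * np.cos(angle),
                               params.cyl_radius * np.sin(angle),
                               params.rise * r])
            u = _recenter(blob, center)
            u.label = f"mt_r{r}_p{p}"
            units.append(u)
    return units


def make_charged_dimer(separation: float = 10.0, q1: float = 1.0,
                       q2: float = -1.0) -> tuple[Unit, Unit]:
    """Two single-site point charges on the x-axis, ``separation`` A apart.

    Charges are stored in the atom's formal-charge slot (independent of
    occupancy); masses are carbon so mass centers are defined.
    """
    if separation <= 0:
        raise ValueError(f"separation must be positive, got {separation}")

    def site(x: float, q: float, label: str) -> Unit:
        atom = Atom(serial=1, name="Q", altloc=" ", resname="CHG",
                    chain_id="A", resseq=1, icode=" ",
                    position=np.array([x, 0.0, 0.0]),
                    element="C", mass=standard_mass("C"), charge=q)
        return Unit([atom], label=label,
                    provenance=[f"synthetic point charge q={q:+g}"])

    return site(0.0, q1, "probe_fixed"), site(separation, q2, "probe_mobile")


def write_icosahedral_capsid_file(path: str | Path,
                                  params: FixtureParams | None = None) -> Path:
    """Write a toy capsomer plus its 60-fold REMARK 350 header to one file.

    The result reads back with :func:`structmanip.pdbio.read_structure` /
    :func:`structmanip.pdbio.parse_biomt` and drives the capsid tools end
    to end with no external data.
    """
    unit = make_toy_capsomer(params)
    matrices = icosahedral_matrices()
    return write_structure(unit, path,
                           header_lines=format_biomt_remarks(matrices))
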