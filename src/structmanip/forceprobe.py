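"""Screened-Coulomb force probe between two units.

A minimal pairwise Debye-Hueckel estimator: each charged residue (or
explicitly charged atom) contributes one point charge, and the force on the
ligand is

    F = sum_ij q_i q_j (1 + kappa r_ij) exp(-kappa r_ij) / (eps r_ij^2) r_hat_ij

in model-internal units (charges in e, distances in A, eps dimensionless).
This is a qualitative consumer for scan outputs — monotone decay, sign of
the radial component, Newton's third law — and is explicitly NOT a
Poisson-Boltzmann solver: no solvation surface, no dielectric boundary, no
claim to physical force magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import GeometryError, mass_center
from .pdbio import Atom, Unit, assign_masses, read_structure

logger = logging.getLogger(__name__)

__all__ = ["ChargeModel", "assign_charges", "net_force", "force_profile"]

#: formal charges at physiological pH; HIS treated neutral, termini ignored
DEFAULT_RESIDUE_CHARGES: dict[str, float] = {
    "ASP": -1.0, "GLU": -1.0, "LYS": +1.0, "ARG": +1.0, "HIS": 0.0,
}

#: atoms of the charged side-chain group, used to place the point charge
_CHARGE_GROUP_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2", "CG"),
    "GLU": ("OE1", "OE2", "CD"),
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE", "CZ"),
}

_STANDARD_RESIDUES = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HOH", "WAT", "CHG",
})


@dataclass
class ChargeModel:
    """Per-residue formal charges plus solvent parameters.

    ``dielectric`` is the relative permittivity (default 80, water);
    ``kappa`` the inverse Debye length in 1/A (default 0: unscreened).
    ``atom_overrides`` maps (chain_id, resseq, atom_name) to a charge that
    supersedes the residue rule.
    """

    residue_charges: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_CHARGES))
    atom_overrides: dict[tuple[str, int, str], float] = field(
        default_factory=dict)
    dielectric: float = 80.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.dielectric <= 0:
            raise ValueError(f"dielectric must be positive, got {self.dielectric}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")


def assign_charges(unit: Unit, model: ChargeModel | None = None) -> Unit:
    """Reduce a unit to its point-charge sites.

    Atoms already carrying a nonzero formal charge (or an explicit override)
    pass through as sites unchanged.  Each residue whose name maps to a
    nonzero formal charge contributes one site at the centroid of its
    charged side-chain group (fallback: the residue centroid).  Unknown
    residue names contribute nothing, with a warning.
    """
    model = model or ChargeModel()
    sites: list[Atom] = []
    residues: dict[tuple[str, int, str, str], list[Atom]] = {}
    unknown: set[str] = set()
    for atom in unit.atoms:
        key = (atom.chain_id, atom.resseq, atom.name)
        if key in model.atom_overrides:
            a = atom.copy()
            a.charge = model.atom_overrides[key]
            sites.append(a)
            continue
        if atom.charge != 0.0:
            sites.append(atom.copy())
            continue
        rkey = (atom.chain_id, atom.resseq, atom.icode, atom.resname)
        residues.setdefault(rkey, []).append(atom)
    for (chain, resseq, icode, resname), atoms in residues.items():
        q = model.residue_charges.get(resname)
        if q is None:
            if resname not in _STANDARD_RESIDUES:
                unknown.add(resname)
            continue
        if q == 0.0:
            continue
        group = _CHARGE_GROUP_ATOMS.get(resname, ())
        chosen = [a for a in atoms if a.name in group] or atoms
        centroid = np.mean([a.position for a in chosen], axis=0)
        sites.append(Atom(
            serial=len(sites) + 1, name="QQ", altloc=" ", resname=resname,
            chain_id=chain, resseq=resseq, icode=icode, position=centroid,
            element="C", mass=12.011, charge=q))
    if unknown:
        logger.warning("unknown residue names treated as neutral: %s",
                       ", ".join(sorted(unknown)))
    return Unit(sites, label=f"{unit.label}|charges",
                provenance=list(unit.provenance) + ["charge sites"])


def _site_arrays(unit: Unit, model: ChargeModel) -> tuple[np.ndarray, np.ndarray]:
    sites = assign_charges(unit, model)
    if not sites.atoms:
        return np.zeros((0, 3)), np.zeros(0)
    return sites.positions, sites.charges


def net_force(receptor: Unit, ligand: Unit,
              model: ChargeModel | None = None) -> np.ndarray:
    """Screened-Coulomb net force on *ligand*, in model units.

    Pairwise over charge sites; antisymmetric, so the force on the receptor
    is the negative.  Raises :class:`GeometryError` when any receptor and
    ligand charge site coincide.
    """
    model = model or ChargeModel()
    pos_r, q_r = _site_arrays(receptor, model)
    pos_l, q_l = _site_arrays(ligand, model)
    if len(q_r) == 0 or len(q_l) == 0:
        return np.zeros(3)
    diff = pos_l[:, None, :] - pos_r[None, :, :]      # ligand j, receptor i
    r = np.linalg.norm(diff, axis=2)
    if np.any(r < 1e-9):
        raise GeometryError("coincident charge sites (r = 0); force diverges")
    qq = q_l[:, None] * q_r[None, :]
    scale = qq * (1.0 + model.kappa * r) * np.exp(-model.kappa * r) \
        / (model.dielectric * r ** 2)
    return (scale[:, :, None] * diff / r[:, :, None]).sum(axis=(0, 1))


def force_profile(manifest, receptor: Unit,
                  model: ChargeModel | None = None,
                  base_dir: str | Path | None = None) -> pd.DataFrame:
    """Evaluate the probe force for every pose of a scan.

    ``manifest`` is a :class:`structmanip.scan.ScanManifest` or a path to a
    manifest TSV; pose filenames resolve against the scan output directory
    (or ``base_dir``).  Returns a DataFrame with columns param, fx, fy, fz,
    mag, radial_sign, where radial_sign is +1 when the force pushes the
    ligand away from the receptor (repulsive), -1 when it pulls it inward
    (attractive).
    """
    model = model or ChargeModel()
    if hasattr(manifest, "rows"):
        rows = [(p, n) for p, n, _, _ in manifest.rows]
        base = Path(base_dir) if base_dir else Path(manifest.spec.out_dir)
    else:
        path = Path(manifest)
        table = pd.read_csv(path, sep="\t", comment="#")
        rows = list(zip(table["param"], table["path"]))
        base = Path(base_dir) if base_dir else path.parent
    c_rec = mass_center(assign_masses(receptor.copy()))
    records = []
    for param, name in rows:
        pose_path = base / name
        if not pose_path.exists():
            raise FileNotFoundError(f"pose file missing: {pose_path}")
        ligand = assign_masses(read_structure(pose_path))
        force = net_force(receptor, ligand, model)
        u_radial = mass_center(ligand) - c_rec
        u_radial /= np.linalg.norm(u_radial)
        radial = float(force @ u_radial)
        records.append({
            "param": float(param),
            "fx": force[0], "fy": force[1], "fz": force[2],
            "mag": float(np.linalg.norm(force)),
            "radial_sign": int(np.sign(radial)),
        })
    return pd.DataFrame.from_records(
        records, columns=["param", "fx", "fy", "fz", "mag", "radial_sign"])
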