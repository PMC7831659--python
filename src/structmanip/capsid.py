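"""Pseudo-spherical assembly tools: capsid generation, expansion, detachment.

A deposited icosahedral capsid file typically contains one capsomer plus the
REMARK 350 BIOMT matrices that place its 60 symmetry copies.  This module

* **generates** the full capsid by applying every BIOMT transform
  (x_f = a x0 + b y0 + c z0 + d, row-wise) to the primary capsomer;
* **expands** it by additionally shifting each copy outward along its radial
  unit vector by a multiple of the mean mass radius R_M (or an absolute
  distance in A);
* **detaches** a single capsomer the same way, leaving the rest in place.

R_M defaults to the symmetric one-step form (capsid center to capsomer
center); the all-atom mass-weighted form is available via ``rm_mode``.
Capsomer indices are 0-based in this API; the CLI is 1-based, matching the
BIOMT matrix numbering in PDB headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np

from . import geometry
from .geometry import GeometryError
from .pdbio import BiomtMatrix, Unit, assign_masses, parse_biomt, read_structure

logger = logging.getLogger(__name__)

__all__ = [
    "CapsidModel",
    "generate_capsid",
    "expand_capsid",
    "detach_capsomer",
    "reference_capsid_report",
]


@dataclass
class CapsidModel:
    """A primary capsomer plus its BIOMT matrices and derived geometry."""

    primary_unit: Unit
    matrices: list[BiomtMatrix]

    def __post_init__(self) -> None:
        if not self.primary_unit.atoms:
            raise GeometryError("primary capsomer has no atoms")
        if not self.matrices:
            raise GeometryError("capsid model requires at least one BIOMT matrix")

    @classmethod
    def from_file(cls, path: str | Path,
                  assembly_id: int | None = None) -> "CapsidModel":
        """Read the primary unit and its BIOMT matrices from one PDB file."""
        unit = assign_masses(read_structure(path))
        matrices = parse_biomt(path, assembly_id=assembly_id)
        return cls(unit, matrices)

    @cached_property
    def primary_center(self) -> np.ndarray:
        return geometry.mass_center(self.primary_unit)

    @cached_property
    def capsomer_centers(self) -> np.ndarray:
        """(N, 3) mass centers of the transformed capsomers.

        Transforming the primary center is exact: a rigid map commutes with
        the mass-weighted average.
        """
        return np.array([m.apply(self.primary_center) for m in self.matrices])

    @cached_property
    def capsid_center(self) -> np.ndarray:
        return geometry.capsid_center(self.capsomer_centers)

    @cached_property
    def radial_units(self) -> np.ndarray:
        """Outward unit vectors, one per capsomer."""
        return geometry.radial_vectors(self.capsid_center, self.capsomer_centers)

    def mean_mass_radius(self, mode: str = "symmetric") -> float:
        """R_M of the assembled capsid.

        ``mode='symmetric'``: distance from the capsid center to the first
        capsomer's center (identical for every capsomer of a symmetric
        shell).  ``mode='atoms'``: mass-weighted mean atom radius over the
        full generated capsid.
        """
        if mode == "symmetric":
            return geometry.mean_mass_radius_symmetric(
                self.capsid_center, self.capsomer_centers[0])
        if mode == "atoms":
            copies = generate_capsid(self.primary_unit, self.matrices)
            return geometry.mean_mass_radius_atoms(copies, self.capsid_center)
        raise ValueError(f"unknown R_M mode {mode!r}; use 'symmetric' or 'atoms'")

    @property
    def R_M(self) -> float:
        return self.mean_mass_radius("symmetric")

    def shift_length(self, fraction: float | None,
                     absolute: float | None, rm_mode: str) -> float:
        """Resolve a shift given either an R_M fraction or absolute A."""
        if (fraction is None) == (absolute is None):
            raise ValueError("give exactly one of fraction (R_M multiples) "
                             "or absolute (A)")
        if absolute is not None:
            return float(absolute)
        return float(fraction) * self.mean_mass_radius(rm_mode)


def generate_capsid(unit: Unit, matrices: list[BiomtMatrix]) -> list[Unit]:
    """Apply every BIOMT matrix to the primary unit; one copy per matrix.

    Output is ordered by matrix index; each copy records its matrix index in
    its provenance and label.
    """
    model = CapsidModel(unit, matrices)
    pos = unit.positions
    copies = []
    for m in model.matrices:
        copies.append(unit.with_positions(
            m.apply(pos),
            note=f"biomt {m.index}",
            label=f"{unit.label}|unit{m.index:03d}"))
    return copies


def expand_capsid(unit: Unit, matrices: list[BiomtMatrix],
                  fraction: float | None = None,
                  absolute: float | None = None,
                  rm_mode: str = "symmetric") -> list[Unit]:
    """Generate the capsid with every capsomer shifted radially outward.

    Each copy n is the BIOMT transform of the primary unit plus an expansion
    vector ``shift * s_hat_n`` where ``s_hat_n`` is the outward unit radial
    vector and ``shift`` is ``fraction * R_M`` (or ``absolute`` A; negative
    values contract).  Each expanded capsomer center then sits at distance
    ``(1 + fraction) * R_M`` from the capsid center.
    """
    model = CapsidModel(unit, matrices)
    shift = model.shift_length(fraction, absolute, rm_mode)
    rm_sym = model.R_M
    logger.info("expansion shift %.3f A (R_M symmetric=%.3f A)", shift, rm_sym)
    pos = unit.positions
    out = []
    for m, s_hat in zip(model.matrices, model.radial_units):
        out.append(unit.with_positions(
            m.apply(pos) + shift * s_hat,
            note=f"biomt {m.index} expand {shift:g}A",
            label=f"{unit.label}|unit{m.index:03d}"))
    return out


def detach_capsomer(unit: Unit, matrices: list[BiomtMatrix], index: int,
                    fraction: float | None = None,
                    absolute: float | None = None,
                    rm_mode: str = "symmetric") -> tuple[Unit, list[Unit]]:
    """Shift one capsomer outward, leave the rest of the capsid in place.

    ``index`` is the 0-based position in the matrix list.  Returns the
    detached capsomer and the remaining capsomers (native positions, matrix
    order preserved).
    """
    model = CapsidModel(unit, matrices)
    if not 0 <= index < len(matrices):
        raise IndexError(
            f"capsomer index {index} out of range 0..{len(matrices) - 1}")
    shift = model.shift_length(fraction, absolute, rm_mode)
    copies = generate_capsid(unit, matrices)
    detached = copies[index].with_positions(
        copies[index].positions + shift * model.radial_units[index],
        note=f"detach {shift:g}A")
    rest = [c for i, c in enumerate(copies) if i != index]
    return detached, rest


def reference_capsid_report(path: str | Path,
                            assembly_id: int | None = None) -> dict[str, float]:
    """Summarize a real capsid deposition (e.g. the TCV entry 3ZX8).

    Returns the symmetric and all-atom mean mass radii, 0.7 R_M (the
    electrostatic effective-range landmark for TCV), and the capsid diameter
    (twice the largest atom radius from the capsid center).
    """
    model = CapsidModel.from_file(path, assembly_id=assembly_id)
    copies = generate_capsid(model.primary_unit, model.matrices)
    center = model.capsid_center
    max_radius = max(
        float(np.linalg.norm(c.positions - center, axis=1).max())
        for c in copies)
    rm_sym = model.mean_mass_radius("symmetric")
    return {
        "n_capsomers": float(len(copies)),
        "R_M_symmetric": rm_sym,
        "R_M_atoms": geometry.mean_mass_radius_atoms(copies, center),
        "0.7_R_M": 0.7 * rm_sym,
        "diameter": 2.0 * max_radius,
    }
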