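"""Mass-weighted centers, coordinate-plane rotations, and capsid geometry.

All lengths are Angstroms, all angles degrees.  Two definitions of the mean
mass radius R_M coexist:

* :func:`mean_mass_radius_atoms` — the mass-weighted mean distance of every
  atom from the capsid center (the general definition);
* :func:`mean_mass_radius_symmetric` — the distance from the capsid center
  to one capsomer's mass center, the one-step simplification valid for a
  symmetric (icosahedral) shell.

They agree only when every atom sits at the same radius; for real capsids
they differ and the capsid tools default to the symmetric form.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
from scipy.spatial.transform import Rotation

from .pdbio import StructureError, Unit

__all__ = [
    "Plane",
    "GeometryError",
    "rotation_matrix",
    "inplane_rotation",
    "mass_center",
    "capsid_center",
    "radial_vectors",
    "mean_mass_radius_atoms",
    "mean_mass_radius_symmetric",
]


class GeometryError(StructureError):
    """A geometric precondition was violated (zero mass, coincident centers...)."""


class Plane(str, Enum):
    """A coordinate plane; rotations in it turn about the perpendicular axis."""

    XY = "xy"
    XZ = "xz"
    YZ = "yz"

    @classmethod
    def of(cls, value: "Plane | str") -> "Plane":
        if isinstance(value, Plane):
            return value
        return cls(str(value).lower())

    @property
    def axis(self) -> str:
        """Name of the perpendicular (rotation) axis."""
        return {"xy": "z", "xz": "y", "yz": "x"}[self.value]

    @property
    def axis_index(self) -> int:
        return {"xy": 2, "xz": 1, "yz": 0}[self.value]

    @property
    def inplane_indices(self) -> tuple[int, int]:
        """Coordinate indices spanning the plane, ascending."""
        return tuple(i for i in range(3) if i != self.axis_index)  # type: ignore[return-value]


def rotation_matrix(plane: Plane | str, angle: float) -> np.ndarray:
    """3x3 rotation by *angle* degrees in *plane* about its perpendicular axis.

    Positive angles are counterclockwise looking down the + perpendicular
    axis (right-hand rule): ``rotation_matrix('xy', 90) @ (1,0,0) = (0,1,0)``.
    """
    plane = Plane.of(plane)
    if not np.isfinite(angle):
        raise GeometryError(f"rotation angle must be finite, got {angle}")
    return Rotation.from_euler(plane.axis, angle % 360.0,
                               degrees=True).as_matrix()


def inplane_rotation(plane: Plane | str, angle: float) -> np.ndarray:
    """The 2x2 block of :func:`rotation_matrix` acting on the in-plane axes."""
    plane = Plane.of(plane)
    idx = plane.inplane_indices
    return rotation_matrix(plane, angle)[np.ix_(idx, idx)]


def mass_center(unit: Unit) -> np.ndarray:
    """Mass-weighted center sum(m_i r_i)/sum(m_i) of a unit, in Angstroms."""
    if not unit.atoms:
        raise GeometryError("mass center of an empty unit is undefined")
    masses = unit.masses
    total = masses.sum()
    if total <= 0:
        raise GeometryError(
            f"unit {unit.label!r} has zero total mass; run assign_masses first")
    return masses @ unit.positions / total


def capsid_center(capsomer_centers: np.ndarray | list) -> np.ndarray:
    """Unweighted arithmetic mean of the capsomer mass centers."""
    centers = np.atleast_2d(np.asarray(capsomer_centers, dtype=float))
    if centers.size == 0:
        raise GeometryError("capsid center of an empty center list is undefined")
    return centers.mean(axis=0)


def radial_vectors(center: np.ndarray,
                   capsomer_centers: np.ndarray | list) -> np.ndarray:
    """Outward unit vectors from the capsid center to each capsomer center.

    These set the direction in which expansion and detachment shift each
    capsomer — away from the capsid center.
    """
    center = np.asarray(center, dtype=float)
    centers = np.atleast_2d(np.asarray(capsomer_centers, dtype=float))
    diffs = centers - center
    norms = np.linalg.norm(diffs, axis=1)
    bad = np.nonzero(norms < 1e-9)[0]
    if bad.size:
        raise GeometryError(
            f"capsomer(s) {bad.tolist()} coincide with the capsid center; "
            "radial direction undefined")
    return diffs / norms[:, None]


def mean_mass_radius_atoms(units: list[Unit] | Unit,
                           center: np.ndarray) -> float:
    """Mean mass radius over all atoms: sum(m_i |r_i - C|)/sum(m_i)."""
    if isinstance(units, Unit):
        units = [units]
    if not units:
        raise GeometryError("mean mass radius of an empty unit list")
    center = np.asarray(center, dtype=float)
    weighted = 0.0
    total = 0.0
    for u in units:
        masses = u.masses
        radii = np.linalg.norm(u.positions - center, axis=1)
        weighted += float(masses @ radii)
        total += float(masses.sum())
    if total <= 0:
        raise GeometryError("zero total mass; run assign_masses first")
    return weighted / total


def mean_mass_radius_symmetric(center: np.ndarray,
                               capsomer_center: np.ndarray) -> float:
    """One-step R_M for a symmetric shell: |C_capsid - C_n|."""
    d = float(np.linalg.norm(np.asarray(capsomer_center, dtype=float)
                             - np.asarray(center, dtype=float)))
    if d < 1e-9:
        raise GeometryError(
            "capsomer center coincides with the capsid center")
    return d
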