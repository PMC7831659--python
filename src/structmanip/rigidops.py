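"""The four basic two-body rigid manipulations.

Every operation takes a *fixed* unit (the receptor, never moved) and a
*manipulated* unit (the ligand) and returns a :class:`PoseResult` holding a
rigidly transformed copy of the manipulated unit:

* :func:`separate` — shift along the mass-center connection line;
* :func:`rotate_about` — rotate about the FIXED unit's mass center;
* :func:`spin` — rotate the unit about its OWN mass center;
* :func:`translate_perpendicular` — shift orthogonally to the mass-center
  line, within a chosen coordinate plane.

Rotation and spin act only on the two in-plane coordinates, so the
perpendicular coordinate of every atom is preserved bit-for-bit (for an
xy-plane spin, every z is untouched).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import GeometryError, Plane, inplane_rotation, mass_center, rotation_matrix
from .pdbio import Unit

logger = logging.getLogger(__name__)

__all__ = [
    "PoseResult",
    "CLASH_THRESHOLD",
    "separate",
    "rotate_about",
    "spin",
    "translate_perpendicular",
    "min_interunit_distance",
]

#: Below this minimum atom-atom distance (A) a pose is flagged as clashing.
CLASH_THRESHOLD = 2.0


@dataclass
class PoseResult:
    """A transformed copy of the manipulated unit plus what was done to it."""

    unit: Unit
    operation: str
    parameters: dict = field(default_factory=dict)
    displacement_of_center: np.ndarray = field(
        default_factory=lambda: np.zeros(3))


def _centers(fixed: Unit, manipulated: Unit) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c_fixed = mass_center(fixed)
    c_man = mass_center(manipulated)
    m_vec = c_man - c_fixed
    if np.linalg.norm(m_vec) < 1e-9:
        raise GeometryError(
            "mass centers of the fixed and manipulated units coincide; "
            "the operation direction is undefined")
    return c_fixed, c_man, m_vec


def separate(fixed: Unit, manipulated: Unit, distance: float) -> PoseResult:
    """Displace the manipulated unit *distance* A along the center line.

    The direction is the unit vector from C_fixed to C_manipulated, so the
    new center separation is the old separation plus *distance* (negative
    distances move the units closer).
    """
    _, _, m_vec = _centers(fixed, manipulated)
    shift = distance * (m_vec / np.linalg.norm(m_vec))
    unit = manipulated.with_positions(
        manipulated.positions + shift,
        note=f"separate d={distance:g}")
    return PoseResult(unit, "separate", {"distance": distance}, shift)


def rotate_about(fixed: Unit, manipulated: Unit, plane: Plane | str,
                 angle: float) -> PoseResult:
    """Rotate the manipulated unit rigidly about the fixed unit's mass center.

    Preserves the center separation and, for every atom, the out-of-plane
    coordinate.  Rotating two overlapping units can create clashes, so
    pre-separating to a safe distance is recommended (a warning is logged
    when the input units are already in contact).
    """
    plane = Plane.of(plane)
    c_fixed, _, _ = _centers(fixed, manipulated)
    if min_interunit_distance(fixed, manipulated) < CLASH_THRESHOLD:
        logger.warning(
            "rotate_about: units are within %.1f A before rotation; "
            "consider separating them first", CLASH_THRESHOLD)
    idx = list(plane.inplane_indices)
    r2 = inplane_rotation(plane, angle)
    pos = manipulated.positions
    new = pos.copy()
    new[:, idx] = (pos[:, idx] - c_fixed[idx]) @ r2.T + c_fixed[idx]
    unit = manipulated.with_positions(
        new, note=f"rotate plane={plane.value} angle={angle:g}")
    disp = mass_center(unit) - mass_center(manipulated)
    return PoseResult(unit, "rotate",
                      {"plane": plane.value, "angle": angle}, disp)


def spin(manipulated: Unit, plane: Plane | str, angle: float) -> PoseResult:
    """Rotate the unit about its own mass center; the center does not move.

    For an xy-plane spin the z coordinate of each atom is exactly the input
    z coordinate (likewise for the perpendicular axis of the other planes).
    """
    plane = Plane.of(plane)
    c = mass_center(manipulated)
    idx = list(plane.inplane_indices)
    r2 = inplane_rotation(plane, angle)
    pos = manipulated.positions
    new = pos.copy()
    new[:, idx] = (pos[:, idx] - c[idx]) @ r2.T + c[idx]
    unit = manipulated.with_positions(
        new, note=f"spin plane={plane.value} angle={angle:g}")
    return PoseResult(unit, "spin",
                      {"plane": plane.value, "angle": angle}, np.zeros(3))


def translate_perpendicular(fixed: Unit, manipulated: Unit,
                            plane: Plane | str, distance: float,
                            sense: int = 90) -> PoseResult:
    """Shift the manipulated unit perpendicular to the mass-center line.

    The in-plane component of the center-to-center vector is normalized,
    scaled by *distance*, then rotated by ``sense`` (+90 or -90 degrees) in
    *plane*; the displacement is therefore orthogonal to the in-plane
    center line.  Fails when the center line is perpendicular to the plane.
    """
    plane = Plane.of(plane)
    if sense not in (90, -90):
        raise GeometryError(f"sense must be +90 or -90 degrees, got {sense}")
    _, _, m_vec = _centers(fixed, manipulated)
    u_inplane = m_vec.copy()
    u_inplane[plane.axis_index] = 0.0
    norm = np.linalg.norm(u_inplane)
    if norm < 1e-9:
        raise GeometryError(
            f"center-to-center vector has no component in the {plane.value} "
            "plane; perpendicular direction undefined")
    shift = rotation_matrix(plane, sense) @ (distance * u_inplane / norm)
    unit = manipulated.with_positions(
        manipulated.positions + shift,
        note=f"perp plane={plane.value} d={distance:g} sense={sense:+d}")
    return PoseResult(unit, "perp",
                      {"plane": plane.value, "distance": distance,
                       "sense": sense}, shift)


def min_interunit_distance(a: Unit, b: Unit) -> float:
    """Minimum atom-atom distance (A) between two units.

    Backed by a k-d tree; used to flag clashes below
    :data:`CLASH_THRESHOLD`.
    """
    if not a.atoms or not b.atoms:
        raise GeometryError("min_interunit_distance requires nonempty units")
    tree = cKDTree(a.positions)
    dists, _ = tree.query(b.positions, k=1)
    return float(dists.min())
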