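"""Fixed-column PDB reading/writing and REMARK 350 BIOMT parsing.

This module deliberately implements the PDB dialect it needs by hand: the
tool's contract is the wwPDB fixed-column layout for ATOM/HETATM records
(coordinates in columns 31-54, 1-based), MODEL/ENDMDL blocks with one block
per assembly unit, and REMARK 350 BIOMT1/2/3 triplets for biological-assembly
transformations.  ATOM and HETATM are both accepted; alternate locations
other than blank/'A' are dropped with a warning; mmCIF is out of scope.

Coordinates are Angstroms in a right-handed frame, unchanged from file.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Unit",
    "BiomtMatrix",
    "StructureError",
    "PDBParseError",
    "PDBWriteError",
    "MassAssignmentError",
    "read_structure",
    "read_models",
    "write_structure",
    "write_structures",
    "parse_biomt",
    "format_biomt_remarks",
    "assign_masses",
    "standard_mass",
    "merge_units",
]


class StructureError(Exception):
    """Base class for all errors raised by this package."""


class PDBParseError(StructureError):
    """A PDB file could not be parsed."""


class PDBWriteError(StructureError):
    """A structure could not be written as PDB."""


class MassAssignmentError(StructureError):
    """Atomic masses could not be assigned."""


# IUPAC 2021 abridged standard atomic weights for the elements common in
# biomolecular structures.  Exotic elements fall back to gemmi's table.
_STANDARD_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45, "BR": 79.904,
    "I": 126.90, "NA": 22.990, "MG": 24.305, "K": 39.098, "CA": 40.078,
    "MN": 54.938, "FE": 55.845, "CO": 58.933, "NI": 58.693, "CU": 63.546,
    "ZN": 65.38, "CD": 112.41, "B": 10.81,
}


def standard_mass(element: str) -> float | None:
    """Standard atomic weight (u) of *element*, or None if unknown."""
    sym = element.strip().upper()
    if not sym:
        return None
    if sym in _STANDARD_MASSES:
        return _STANDARD_MASSES[sym]
    try:
        from gemmi import Element
    except ImportError:  # pragma: no cover
        return None
    el = Element(sym.capitalize())
    if el.name == "X" and sym != "X":
        return None
    return float(el.weight) if el.weight > 0 else None


@dataclass
class Atom:
    """One PDB atom record.

    ``mass`` is in unified atomic mass units and is 0.0 until
    :func:`assign_masses` runs; ``charge`` is a formal charge in units of e
    (PDB columns 79-80), used by the force probe.
    """

    serial: int
    name: str
    altloc: str
    resname: str
    chain_id: str
    resseq: int
    icode: str
    position: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    element: str = ""
    mass: float = 0.0
    charge: float = 0.0
    het: bool = False

    def copy(self) -> "Atom":
        return replace(self, position=np.array(self.position, dtype=float))


@dataclass
class Unit:
    """An ordered atom collection representing one rigid biomolecule.

    A Unit is what every geometric operation acts on: a capsomer, a kinesin
    motor domain, a tubulin subunit.  ``provenance`` records the source path
    and every operation applied, oldest first.
    """

    atoms: list[Atom]
    label: str = ""
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstroms (a fresh copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain identifiers, in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def copy(self, note: str | None = None) -> "Unit":
        u = Unit([a.copy() for a in self.atoms], self.label, list(self.provenance))
        if note:
            u.provenance.append(note)
        return u

    def with_positions(self, positions: np.ndarray, note: str | None = None,
                       label: str | None = None) -> "Unit":
        """A copy of this unit with new coordinates, same atom order/fields."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise ValueError(
                f"positions shape {positions.shape} does not match "
                f"{len(self.atoms)} atoms")
        atoms = [replace(a, position=positions[i].copy())
                 for i, a in enumerate(self.atoms)]
        u = Unit(atoms, label if label is not None else self.label,
                 list(self.provenance))
        if note:
            u.provenance.append(note)
        return u


@dataclass
class BiomtMatrix:
    """One REMARK 350 transformation: 3x3 rotation block + translation (A).

    Row ``BIOMT1`` supplies (a, b, c, d), ``BIOMT2`` (e, f, g, h) and
    ``BIOMT3`` (i, j, k, l); a-c/e-g/i-k form ``rotation`` and d, h, l form
    ``translation``, so a transformed coordinate is
    ``x_f = a*x0 + b*y0 + c*z0 + d`` (and likewise for y, z).
    """

    index: int
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.rotation))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array (or a single 3-vector)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------

def _infer_element(name: str) -> str:
    """Element from the first alphabetic character of the atom name.

    Follows the alpha-carbon convention (" CA " is carbon); two-letter
    elements must use the explicit element columns to be recognized.
    """
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int, path: Path) -> Atom:
    line = line.rstrip("\n")
    padded = line.ljust(80)
    try:
        x = float(padded[30:38])
        y = float(padded[38:46])
        z = float(padded[46:54])
    except ValueError as exc:
        raise PDBParseError(
            f"{path}: malformed coordinate field on line {lineno}: "
            f"{line!r}") from exc
    if not np.all(np.isfinite([x, y, z])):
        raise PDBParseError(
            f"{path}: non-finite coordinate on line {lineno}")

    def _int(fieldstr: str, default: int = 0) -> int:
        fieldstr = fieldstr.strip()
        return int(fieldstr) if fieldstr else default

    def _float(fieldstr: str, default: float = 0.0) -> float:
        fieldstr = fieldstr.strip()
        return float(fieldstr) if fieldstr else default

    element = padded[76:78].strip()
    name = padded[12:16].strip()
    if not element:
        element = _infer_element(name)
    charge_field = padded[78:80].strip()
    charge = 0.0
    if charge_field:
        try:
            # PDB writes "1-", "2+"; tolerate "+1"/"-1" as well.
            if charge_field[-1] in "+-":
                charge = float(charge_field[-1] + charge_field[:-1])
            else:
                charge = float(charge_field)
        except ValueError:
            logger.warning("%s: unparseable charge %r on line %d",
                           path, charge_field, lineno)
    return Atom(
        serial=_int(padded[6:11]),
        name=name,
        altloc=padded[16],
        resname=padded[17:20].strip(),
        chain_id=padded[21],
        resseq=_int(padded[22:26]),
        icode=padded[26],
        position=np.array([x, y, z], dtype=float),
        occupancy=_float(padded[54:60], 1.0),
        bfactor=_float(padded[60:66], 0.0),
        element=element,
        charge=charge,
        het=line.startswith("HETATM"),
    )


def _read_all_models(path: str | Path,
                     chain_filter: set[str] | None) -> list[list[Atom]]:
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"file not found: {path}")
    models: list[list[Atom]] = []
    current: list[Atom] = []
    saw_model_record = False
    n_altloc_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_record = True
                if current:
                    models.append(current)
                    current = []
            elif rec == "ENDMDL":
                models.append(current)
                current = []
            elif line.startswith(("ATOM  ", "HETATM")):
                atom = _parse_atom_line(line, lineno, path)
                if atom.altloc not in (" ", "", "A"):
                    n_altloc_dropped += 1
                    continue
                if chain_filter is not None and atom.chain_id not in chain_filter:
                    continue
                current.append(atom)
    if current or not models:
        models.append(current)
    if n_altloc_dropped:
        logger.warning("%s: dropped %d alternate-location atoms (altloc not "
                       "blank/'A')", path, n_altloc_dropped)
    models = [m for m in models if m]
    if not models:
        detail = " after chain filtering" if chain_filter is not None else ""
        raise PDBParseError(f"{path}: no parsable ATOM/HETATM records{detail}")
    if saw_model_record:
        logger.debug("%s: %d MODEL blocks read", path, len(models))
    return models


def read_structure(path: str | Path,
                   chain_filter: set[str] | None = None) -> Unit:
    """Read a PDB file into a single :class:`Unit`, atoms in file order.

    If the file contains MODEL/ENDMDL blocks only the first model is
    returned (use :func:`read_models` for all of them).  ``chain_filter``
    keeps only atoms whose chain identifier is in the given set.

    Raises :class:`PDBParseError` when no atom record survives parsing and
    filtering, or when a coordinate field is malformed.
    """
    models = _read_all_models(path, chain_filter)
    unit = Unit(models[0], label=Path(path).stem,
                provenance=[f"read {Path(path)}"])
    return unit


def read_models(path: str | Path,
                chain_filter: set[str] | None = None) -> list[Unit]:
    """Read every MODEL block of a PDB file as its own :class:`Unit`."""
    models = _read_all_models(path, chain_filter)
    stem = Path(path).stem
    return [Unit(atoms, label=f"{stem}#{i + 1}",
                 provenance=[f"read {Path(path)} model {i + 1}"])
            for i, atoms in enumerate(models)]


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------

def _format_charge(charge: float) -> str:
    if charge == 0:
        return "  "
    mag = int(round(abs(charge)))
    if mag == 0 or abs(charge - round(charge)) > 1e-9 or mag > 9:
        return "  "  # fractional/out-of-range charges are not representable
    return f"{mag}{'+' if charge > 0 else '-'}"


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    # one-letter elements start in column 14 per the wwPDB layout
    if len(element) == 1 and name.upper().startswith(element.upper()):
        return f" {name:<3s}"
    if len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def _format_atom_line(atom: Atom) -> str:
    for c in atom.position:
        if not np.isfinite(c) or abs(c) >= 10000.0 or c <= -1000.0:
            raise PDBWriteError(
                f"coordinate {c:.3f} of atom serial {atom.serial} overflows "
                "the 8-column PDB coordinate field")
    record = "HETATM" if atom.het else "ATOM  "
    x, y, z = atom.position
    return (
        f"{record}{min(atom.serial, 99999):>5d} "
        f"{_format_atom_name(atom.name, atom.element)}"
        f"{(atom.altloc or ' ')[:1]}"
        f"{atom.resname:>3.3s} "
        f"{(atom.chain_id or ' ')[:1]}"
        f"{atom.resseq:>4d}"
        f"{(atom.icode or ' ')[:1]}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}"
        f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}          "
        f"{atom.element:>2.2s}{_format_charge(atom.charge)}"
    )


def _unit_lines(unit: Unit) -> list[str]:
    lines = [_format_atom_line(a) for a in unit.atoms]
    last = unit.atoms[-1]
    lines.append(
        f"TER   {min(last.serial + 1, 99999):>5d}      {last.resname:>3.3s} "
        f"{(last.chain_id or ' ')[:1]}{last.resseq:>4d}{(last.icode or ' ')[:1]}"
    )
    return lines


def write_structure(unit: Unit, path: str | Path,
                    header_lines: list[str] | None = None) -> Path:
    """Write one unit as a standard fixed-column PDB file (ATOM/TER/END).

    ``header_lines`` (e.g. REMARK 350 records) are emitted verbatim before
    the coordinate section.  Raises :class:`PDBWriteError` on an empty unit
    or on coordinates that overflow the 8-column field.
    """
    if not unit.atoms:
        raise PDBWriteError(f"refusing to write empty unit to {path}")
    path = Path(path)
    lines = list(header_lines or [])
    lines += _unit_lines(unit)
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_structures(units: list[Unit], path: str | Path,
                     header_lines: list[str] | None = None) -> Path:
    """Write several units into one PDB file, one MODEL block per unit."""
    if not units or any(not u.atoms for u in units):
        raise PDBWriteError(f"refusing to write empty unit(s) to {path}")
    path = Path(path)
    lines = list(header_lines or [])
    for i, unit in enumerate(units, start=1):
        lines.append(f"MODEL     {i:>4d}")
        lines += _unit_lines(unit)
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def merge_units(units: list[Unit], label: str = "merged") -> Unit:
    """Concatenate several units into one (atom order: unit order)."""
    atoms: list[Atom] = []
    for u in units:
        atoms.extend(a.copy() for a in u.atoms)
    prov = [f"merged {len(units)} units"]
    return Unit(atoms, label=label, provenance=prov)


# --------------------------------------------------------------------------
# REMARK 350 BIOMT
# --------------------------------------------------------------------------

def parse_biomt(path: str | Path,
                assembly_id: int | None = None) -> list[BiomtMatrix]:
    """Parse REMARK 350 BIOMT matrices from a PDB file.

    Rows are assembled per matrix index N from the BIOMT1/BIOMT2/BIOMT3
    triplet.  When the header defines several BIOMOLECULE blocks the block
    whose number equals ``assembly_id`` is used (default: the first block).

    Raises :class:`PDBParseError` if the file has no REMARK 350 records, the
    requested assembly is absent, or a triplet is incomplete.
    """
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"file not found: {path}")
    # block id -> {N -> {row -> (4 floats)}}
    blocks: dict[int, dict[int, dict[int, tuple[float, ...]]]] = {}
    order: list[int] = []
    current_block: int | None = None
    saw_remark350 = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("REMARK 350"):
                continue
            saw_remark350 = True
            if "BIOMOLECULE:" in line:
                try:
                    current_block = int(line.split("BIOMOLECULE:")[1].split()[0])
                except (IndexError, ValueError) as exc:
                    raise PDBParseError(
                        f"{path}: malformed BIOMOLECULE record on line "
                        f"{lineno}") from exc
                if current_block not in blocks:
                    blocks[current_block] = {}
                    order.append(current_block)
                continue
            tokens = line.split()
            if len(tokens) >= 8 and tokens[2].startswith("BIOMT"):
                try:
                    row = int(tokens[2][5:])
                    n = int(tokens[3])
                    vals = tuple(float(t) for t in tokens[4:8])
                except ValueError as exc:
                    raise PDBParseError(
                        f"{path}: malformed BIOMT record on line "
                        f"{lineno}") from exc
                if current_block is None:
                    current_block = 1
                    blocks[current_block] = {}
                    order.append(current_block)
                blocks[current_block].setdefault(n, {})[row] = vals
    if not saw_remark350 or not blocks:
        raise PDBParseError(f"{path}: no REMARK 350 BIOMT records found")
    if assembly_id is None:
        block = blocks[order[0]]
    elif assembly_id in blocks:
        block = blocks[assembly_id]
    else:
        raise PDBParseError(
            f"{path}: no BIOMOLECULE block {assembly_id} "
            f"(available: {sorted(blocks)})")
    matrices: list[BiomtMatrix] = []
    for n in sorted(block):
        rows = block[n]
        missing = [r for r in (1, 2, 3) if r not in rows]
        if missing:
            raise PDBParseError(
                f"{path}: incomplete BIOMT triplet for matrix {n} "
                f"(missing BIOMT{'/BIOMT'.join(map(str, missing))})")
        rot = np.array([rows[r][:3] for r in (1, 2, 3)], dtype=float)
        trans = np.array([rows[r][3] for r in (1, 2, 3)], dtype=float)
        m = BiomtMatrix(index=n, rotation=rot, translation=trans)
        if abs(m.det - 1.0) > 1e-3:
            warnings.warn(
                f"BIOMT matrix {n} in {path} has det {m.det:.6f} != 1; "
                "biological assemblies normally use proper rotations",
                stacklevel=2)
        matrices.append(m)
    return matrices


def format_biomt_remarks(matrices: list[BiomtMatrix],
                         biomolecule: int = 1) -> list[str]:
    """Render matrices as REMARK 350 header lines (parse_biomt-compatible)."""
    lines = [f"REMARK 350 BIOMOLECULE: {biomolecule}"]
    for m in matrices:
        for row in range(3):
            a, b, c = m.rotation[row]
            d = m.translation[row]
            lines.append(
                f"REMARK 350   BIOMT{row + 1} {m.index:3d}"
                f"{a:10.6f}{b:10.6f}{c:10.6f}{d:15.5f}")
    return lines


# --------------------------------------------------------------------------
# Masses
# --------------------------------------------------------------------------

def assign_masses(unit: Unit,
                  mass_table: dict[str, float] | None = None) -> Unit:
    """Assign per-atom masses (u) from the standard atomic weights.

    The element symbol parsed from columns 77-78 (or inferred from the atom
    name) is looked up in ``mass_table`` (default: standard atomic weights).
    An element missing from the table falls back to the first alphabetic
    character of the atom name, with a logged warning.  Idempotent; mutates
    and returns ``unit``.

    Raises :class:`MassAssignmentError` listing the offending atoms when
    neither lookup resolves.
    """
    table = {k.upper(): v for k, v in mass_table.items()} if mass_table else None

    def lookup(sym: str) -> float | None:
        if table is not None:
            return table.get(sym.upper())
        return standard_mass(sym)

    unresolved: list[str] = []
    n_fallback = 0
    for atom in unit.atoms:
        mass = lookup(atom.element) if atom.element else None
        if mass is None:
            fallback = _infer_element(atom.name)
            mass = lookup(fallback) if fallback else None
            if mass is not None:
                n_fallback += 1
        if mass is None:
            unresolved.append(
                f"serial {atom.serial} name {atom.name!r} "
                f"element {atom.element!r}")
        else:
            atom.mass = mass
    if n_fallback:
        logger.warning("%d atoms had no usable element symbol; mass inferred "
                       "from the atom name", n_fallback)
    if unresolved:
        raise MassAssignmentError(
            "could not assign a mass to " + "; ".join(unresolved))
    return unit
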