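"""Batch pose-series generation over distance/angle grids.

A :class:`ScanSpec` names one operation (separate, rotate, spin, perp,
detach), an inclusive parameter grid ``start, start+step, ..., stop``, and
the input structures; :func:`run_scan` writes one PDB pose per grid point
plus a tab-separated manifest that downstream electrostatics tools (e.g. a
Poisson-Boltzmann force pipeline) can consume.

Every pose is generated independently from the original input at its
absolute grid value — never cumulatively — so floating-point error does not
accumulate and reruns are byte-identical.

:func:`preset_protocols` returns the seven standard sweeps used for the
viral-capsid and kinesin-microtubule studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .capsid import CapsidModel, detach_capsomer
from .geometry import Plane
from .pdbio import (StructureError, Unit, assign_masses, merge_units,
                    read_structure, write_structure, write_structures)
from .rigidops import (CLASH_THRESHOLD, min_interunit_distance, rotate_about,
                       separate, spin, translate_perpendicular)

logger = logging.getLogger(__name__)

__all__ = ["ScanSpec", "ScanManifest", "run_scan", "preset_protocols",
           "PRESET_NAMES"]

_OPS = ("separate", "rotate", "spin", "perp", "detach")


@dataclass
class ScanSpec:
    """One parameter sweep: operation, inclusive grid, inputs, outputs.

    Units of ``start/stop/step``: Angstroms for separate/perp, degrees for
    rotate/spin, R_M fractions for detach.
    """

    op: str
    start: float
    stop: float
    step: float
    plane: Plane = Plane.XY
    sense: int = 90
    fixed_path: str | None = None
    mobile_path: str | None = None
    capsid_path: str | None = None
    assembly_id: int | None = None
    index: int = 0
    out_dir: str = "."
    name_template: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown scan op {self.op!r}; one of {_OPS}")
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if self.stop < self.start:
            raise ValueError(f"stop {self.stop} < start {self.start}")
        self.plane = Plane.of(self.plane)

    def grid(self) -> np.ndarray:
        """start, start+step, ..., inclusive of stop when reachable."""
        n = int(math.floor((self.stop - self.start) / self.step + 1e-9))
        return self.start + self.step * np.arange(n + 1)

    def pose_name(self, param: float) -> str:
        template = self.name_template or "{op}_{param:+09.3f}.pdb"
        return template.format(op=self.op, param=param)


@dataclass
class ScanManifest:
    """The record of one executed scan: one row per generated pose."""

    spec: ScanSpec
    #: rows of (parameter value, pose filename, min inter-unit distance A,
    #: clash flag); min_dist is NaN when no reference unit exists (bare spin)
    rows: list[tuple[float, str, float, bool]] = field(default_factory=list)
    version: str = __version__

    def __len__(self) -> int:
        return len(self.rows)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"# structmanip {self.version}",
                 f"# op: {self.spec.op}",
                 f"# grid: {self.spec.start:g} to {self.spec.stop:g} "
                 f"step {self.spec.step:g}",
                 f"# plane: {self.spec.plane.value}",
                 "param\tpath\tmin_dist\tclash"]
        for param, name, min_dist, clash in self.rows:
            md = "nan" if math.isnan(min_dist) else f"{min_dist:.3f}"
            lines.append(f"{param:g}\t{name}\t{md}\t{int(clash)}")
        path.write_text("\n".join(lines) + "\n")
        return path


def _pose_for(spec: ScanSpec, param: float, fixed: Unit | None,
              mobile: Unit | None, model: CapsidModel | None,
              rest_merged: Unit | None) -> tuple[Unit, Unit | None]:
    """(pose unit to write, reference unit for the clash check)."""
    if spec.op == "separate":
        return separate(fixed, mobile, param).unit, fixed
    if spec.op == "rotate":
        return rotate_about(fixed, mobile, spec.plane, param).unit, fixed
    if spec.op == "spin":
        return spin(mobile, spec.plane, param).unit, fixed
    if spec.op == "perp":
        return translate_perpendicular(
            fixed, mobile, spec.plane, param, sense=spec.sense).unit, fixed
    if spec.op == "detach":
        detached, _ = detach_capsomer(
            model.primary_unit, model.matrices, spec.index, fraction=param)
        return detached, rest_merged
    raise AssertionError(spec.op)


def run_scan(spec: ScanSpec) -> ScanManifest:
    """Execute a sweep: write one pose per grid point plus ``manifest.tsv``.

    Per-pose clashes (minimum atom-atom distance below 2.0 A) are recorded
    in the manifest and logged as warnings; the run continues.
    """
    out_dir = Path(spec.out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise StructureError(f"cannot create output directory {out_dir}: "
                             f"{exc}") from exc

    fixed = mobile = rest_merged = None
    model = None
    if spec.op == "detach":
        if not spec.capsid_path:
            raise ValueError("detach scan requires capsid_path")
        model = CapsidModel.from_file(spec.capsid_path,
                                      assembly_id=spec.assembly_id)
        _, rest = detach_capsomer(model.primary_unit, model.matrices,
                                  spec.index, fraction=0.0)
        write_structures(rest, out_dir / "rest.pdb")
        rest_merged = merge_units(rest, label="rest")
    else:
        if not spec.mobile_path:
            raise ValueError(f"{spec.op} scan requires mobile_path")
        mobile = assign_masses(read_structure(spec.mobile_path))
        if spec.fixed_path:
            fixed = assign_masses(read_structure(spec.fixed_path))
        elif spec.op != "spin":
            raise ValueError(f"{spec.op} scan requires fixed_path")

    manifest = ScanManifest(spec)
    for param in spec.grid():
        pose, ref = _pose_for(spec, float(param), fixed, mobile, model,
                              rest_merged)
        name = spec.pose_name(float(param))
        write_structure(pose, out_dir / name)
        if ref is not None:
            min_dist = min_interunit_distance(ref, pose)
        else:
            min_dist = float("nan")
        clash = bool(min_dist < CLASH_THRESHOLD)
        if clash:
            logger.warning("clash at %s=%g: min distance %.3f A < %.1f A",
                           spec.op, param, min_dist, CLASH_THRESHOLD)
        manifest.rows.append((float(param), name, min_dist, clash))
    manifest.write(out_dir / "manifest.tsv")
    return manifest


# --------------------------------------------------------------------------
# Presets: the seven standard sweeps
# --------------------------------------------------------------------------

_PRESETS: dict[str, ScanSpec] = {
    # one capsomer vs the rest of an icosahedral capsid
    "capsomer-detach": ScanSpec("detach", 0.4, 1.0, 0.1,
                                name="capsomer-detach"),
    "capsomer-spin": ScanSpec("spin", -90.0, 90.0, 2.0, plane=Plane.XY,
                              name="capsomer-spin"),
    "capsomer-rotate": ScanSpec("rotate", -20.0, 20.0, 2.0, plane=Plane.XY,
                                name="capsomer-rotate"),
    # kinesin motor domain vs a microtubule (axis = z)
    "kinesin-separate": ScanSpec("separate", 5.0, 50.0, 2.0,
                                 name="kinesin-separate"),
    "kinesin-rotate": ScanSpec("rotate", -20.0, 50.0, 2.0, plane=Plane.XZ,
                               name="kinesin-rotate"),
    "kinesin-spin": ScanSpec("spin", -180.0, 180.0, 2.0, plane=Plane.XY,
                             name="kinesin-spin"),
    "kinesin-translate": ScanSpec("perp", -80.0, 80.0, 2.0, plane=Plane.XZ,
                                  name="kinesin-translate"),
}

PRESET_NAMES = tuple(_PRESETS)


def preset_protocols() -> list[ScanSpec]:
    """The seven standard sweeps (grids fixed; paths/outputs to be filled).

    Capsomer series: detach 0.4-1.0 R_M step 0.1; spin -90..90 deg step 2;
    rotate -20..20 deg step 2.  Kinesin series: separate 5-50 A step 2;
    rotate -20..50 deg step 2; spin -180..180 deg step 2; perpendicular
    translation -80..80 A step 2.
    """
    return [replace(spec) for spec in _PRESETS.values()]


def get_preset(name: str) -> ScanSpec:
    try:
        return replace(_PRESETS[name])
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(_PRESETS)}"
        ) from None
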