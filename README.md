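# structmanip

Rigid-body structure manipulation for large biomolecular assemblies.

Studying interactions in very large complexes — a viral capsid, a molecular
motor walking on a microtubule — usually means generating many poses of one
unit relative to another and feeding them to an electrostatics or scoring
pipeline. `structmanip` is the pose-generation half of that workflow: a
Python library and CLI that reads PDB coordinate files, applies exact
rigid-body operations between a receptor and a ligand, assembles and
deforms icosahedral capsids from their REMARK 350 BIOMT matrices, and
writes batch pose series with machine-readable manifests.

It is aimed at computational structural biologists who need reproducible,
scriptable structure manipulation at assembly scale, without a molecular
viewer in the loop.

## What it computes

**Two-body operations.** For a fixed unit and a manipulated unit with
mass-weighted centers C_f and C_m (masses are standard atomic weights):

* *separation* — shift the ligand by d·û along û = (C_m − C_f)/|C_m − C_f|;
* *rotation* — rotate the ligand rigidly about C_f in a coordinate plane
  (xy, xz or yz; right-hand rule about the perpendicular axis);
* *spin* — rotate the ligand about its **own** mass center (the
  perpendicular coordinate of every atom is preserved bit-for-bit);
* *perpendicular translation* — shift the ligand orthogonally to the
  in-plane component of the center line.

All four are exactly rigid: intra-unit distances are preserved to well
below 1e-6 Å.

**Capsid tools.** A BIOMT matrix N with rotation block (a…k) and
translation (d, h, l) maps each atom by x_f = a·x₀ + b·y₀ + c·z₀ + d (rows
2, 3 likewise). From the primary capsomer the tools derive the capsid
center C_capsid (mean of the transformed capsomer centers), the outward
radial unit vectors ŝ_n, and the **mean mass radius**

* R_M = Σᵢ mᵢ·rᵢ / M_T over all atoms (general form), or
* R_M = |C_capsid − C_n| (one-step form, exact for a symmetric shell;
  the default for the capsid tools).

*Expansion* adds f·R_M·ŝ_n to every capsomer after its BIOMT transform, so
each center moves to (1+f)·R_M; *detachment* applies the same shift to one
chosen capsomer only and writes the rest of the capsid separately.

**Scans.** `run_scan` sweeps any operation over an inclusive grid
(start, start+step, …), generating each pose independently from the
original input so reruns are byte-identical, and records per-pose minimum
inter-unit distances and clash flags (< 2 Å) in a TSV manifest. Seven
preset sweeps cover the standard capsomer series (detach 0.4–1.0 R_M,
spin −90°..90°, rotate −20°..20°) and kinesin–microtubule series
(separate 5–50 Å, rotate −20°..50°, spin −180°..180°, translate −80..80 Å),
all on 2-unit grids.

**Force probe.** A screened-Coulomb (Debye–Hückel) pairwise estimator over
per-residue formal charges classifies scan poses as attractive/repulsive
and checks monotone decay. It is a qualitative consumer for scan outputs,
*not* a Poisson–Boltzmann solver.

**Synthetic fixtures.** Seeded generators build toy capsomers, the exact
60-element icosahedral rotation group as BIOMT matrices, microtubule-like
cylindrical lattices and charged dimers, so the whole pipeline runs and is
tested with no downloads.

## Worked example

```python
from structmanip.fixtures import FixtureParams, write_icosahedral_capsid_file
from structmanip.capsid import CapsidModel, detach_capsomer
from structmanip.geometry import mass_center
import numpy as np

path = write_icosahedral_capsid_file("toy_capsid.pdb", FixtureParams(seed=42))
model = CapsidModel.from_file(path)
print(f"capsomers: {len(model.matrices)}")
print(f"R_M (symmetric): {model.R_M:.3f} A")
detached, rest = detach_capsomer(model.primary_unit, model.matrices, 12,
                                 fraction=0.4)
r = np.linalg.norm(mass_center(detached) - model.capsid_center)
print(f"detached center at {r / model.R_M:.3f} R_M; rest: {len(rest)} units")
```

prints

```
capsomers: 60
R_M (symmetric): 100.000 A
detached center at 1.400 R_M; rest: 59 units
```

60 symmetry copies tile the shell (3 chains each → 180 subunit chains), the
toy capsomer sits at the stated 100 Å shell radius, and a 0.4 R_M
detachment lands its center at exactly 1.4 R_M from the capsid center.

The same flow from the shell:

```bash
structmanip fixture icosa-capsid --seed 42 --out toy_capsid.pdb
structmanip capsid generate toy_capsid.pdb --out-dir capsid/
structmanip scan --preset capsomer-detach --capsid toy_capsid.pdb --out-dir detach/
structmanip probe-force --receptor detach/rest.pdb --manifest detach/manifest.tsv --out forces.tsv
```

If you have a real icosahedral deposition (e.g. the turnip crinkle virus
capsid, PDB 3ZX8), `structmanip.capsid.reference_capsid_report(path)`
reports its capsomer count, both mean-mass-radius forms and the capsid
diameter.

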