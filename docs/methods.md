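# Methods

This document records the model, the conventions that are not visible from
the API alone, and the limitations of the synthetic data generators.

## Coordinate model and I/O

Structures are read and written in fixed-column PDB format. Coordinates
occupy columns 31–54 (1-based), the element symbol columns 77–78, and an
optional formal charge columns 79–80. Multi-model files are read via
MODEL/ENDMDL. Alternate locations other than blank or `A` are dropped with
a warning, so every atom appears exactly once. Writing rejects coordinates
outside the representable fixed-column range (≥ 10000 or ≤ −1000 Å).
Written coordinates carry 3 decimals, so a read–write round trip preserves
positions to ≤ 5·10⁻⁴ Å; all tolerances downstream of file round trips
account for this quantization.

Masses are assigned from a built-in table of standard atomic weights
(IUPAC 2021 abridged values, e.g. C = 12.011, N = 14.007, O = 15.999,
S = 32.06), with a fallback lookup through `gemmi` for elements outside
the table. When the element field is blank, the element is inferred from
the first alphabetic character of the atom name.

## Rigid-body operations

A *unit* is any set of atoms moved as one rigid body. All operations are
parameterized by a coordinate plane (xy, xz, or yz); angles are in
degrees, distances in Å. Angles follow the right-hand rule about the axis
perpendicular to the plane (+z for xy, +y for xz, +x for yz).

* **Separation**: translate the mobile unit by d·û with
  û = (C_m − C_f)/|C_m − C_f|, where C_f and C_m are the mass-weighted
  centers of the fixed and mobile units. Negative d moves the units
  together. Coincident centers (|C_m − C_f| < 10⁻⁹ Å) are an error.
* **Rotation about the fixed unit**: the two in-plane coordinates of each
  atom are rotated by the 2×2 block of the rotation matrix about C_f; the
  perpendicular coordinate column is not touched, so it is preserved
  bitwise, not merely to rounding.
* **Spin**: same construction about the mobile unit's own mass center.
* **Perpendicular translation**: the mobile unit is shifted along the
  in-plane component of the center line rotated by ±90° in the plane
  (sense selectable), i.e. orthogonally to the receptor–ligand axis while
  staying in the chosen plane.

Each operation returns the new unit together with the operation name, its
parameters, and the displacement of the mass center. Minimum inter-unit
atom distance is computed with a k-d tree; a distance below the clash
threshold (default 2.0 Å, roughly two covalent radii) produces a warning
and a manifest flag but never aborts — steric overlap is often exactly
the regime a scan is meant to map.

## Capsid construction

A capsid file supplies one capsomer (the primary unit) plus REMARK 350
BIOMT1/2/3 triplets. When several biological assemblies are present, one
is selected by its BIOMOLECULE id (default: the first). Each matrix N is a
rotation block plus translation applied as x_f = a·x₀ + b·y₀ + c·z₀ + d
(and likewise for y, z). Rotation blocks whose determinant differs from
±1 by more than 10⁻³ trigger a warning.

Derived quantities, for n = 1…N capsomer copies with mass centers C_n:

* capsid center C_capsid = (1/N) Σ C_n;
* outward radial unit vectors ŝ_n = (C_n − C_capsid)/|C_n − C_capsid|
  (the sign convention is *outward*: positive shift fractions move
  capsomers away from the center);
* mean mass radius, two estimators:
  * **all-atom**: R_M = Σᵢ mᵢ·|xᵢ − C_capsid| / Σᵢ mᵢ over every atom of
    every copy;
  * **symmetric** (default): R_M = |C_n − C_capsid|, identical for all n
    under exact point-group symmetry. For a real, imperfect shell the two
    differ; the symmetric form is used by the capsid tools because shift
    lengths are defined relative to capsomer-center radii.

**Expansion** by fraction f moves every copy by f·R_M·ŝ_n after its BIOMT
transform; since ŝ_n is a unit vector the shift has length exactly f·R_M,
and each capsomer center lands at radius (1+f)·R_M. **Detachment** applies
the same shift to a single chosen copy and returns the remaining N−1
copies unchanged. An absolute shift in Å may be given instead of a
fraction (exactly one of the two). The acceptance landmarks follow:
f = 0.4 puts the detached center at 1.4 R_M and f = 1.0 at 2.0 R_M, both
verified to a relative tolerance of 10⁻⁶ in the test suite.

## Scans

A scan sweeps one operation over the inclusive grid start, start+step, …
The endpoint is included when (stop − start)/step is integral (to within
10⁻⁹ relative); otherwise the last point sits one step short — e.g. the
5→50 Å step-2 separation sweep ends at 49 Å with 23 poses. Every pose is
generated *absolutely* from the original input at its own parameter value
(never cumulatively from the previous pose), so per-pose error does not
accumulate and a rerun with identical arguments is byte-identical. The
manifest (TSV: parameter, filename, minimum inter-unit distance, clash
flag) deliberately contains no timestamps or hostnames for the same
reason.

The seven presets encode two published-style protocols, all on 2-unit
grids:

| preset | operation | range | poses |
|---|---|---|---|
| capsomer-detach | detach | 0.4–1.0 R_M, step 0.1 | 7 |
| capsomer-spin | spin | −90°…90° | 91 |
| capsomer-rotate | rotate | −20°…20° | 21 |
| kinesin-separate | separate | 5–50 Å (last point 49) | 23 |
| kinesin-rotate | rotate | −20°…50° | 36 |
| kinesin-spin | spin | −180°…180° | 181 |
| kinesin-translate | perpendicular | −80…80 Å | 81 |

The kinesin presets default to the xz plane, matching a microtubule whose
long axis is z: rotations and spins then tilt the motor within the plane
containing the radial and axial directions, and the perpendicular
translation slides it along the filament surface.

## Force probe

The probe assigns formal charges per residue (ASP, GLU → −1; LYS, ARG →
+1; HIS → 0 at neutral pH) placed at the centroid of the side-chain
charged group, with explicit per-atom charges and user overrides taking
precedence. The interaction is a screened Coulomb (Debye–Hückel) sum,

F⃗ = Σᵢⱼ qᵢqⱼ (1 + κr) e^(−κr) / (ε r²) · r̂ᵢⱼ,

with relative dielectric ε = 80 and inverse screening length κ = 0 Å⁻¹
(plain Coulomb) by default. Output per pose: force components, magnitude,
and a radial sign (+1 repulsive, −1 attractive, by projection onto the
center line). This is a qualitative ranking tool: no solvation surface,
no induced polarization, no pH titration. It exists so that scan outputs
can be consumed end to end; a Poisson–Boltzmann solver should replace it
for quantitative work.

## Synthetic fixtures

All generators are seeded (`numpy.random.default_rng`) and deterministic.

* **Icosahedral matrices**: the 60 proper rotations of the icosahedral
  group, obtained from `scipy.spatial.transform.Rotation.create_group("I")`
  and deterministically ordered with the identity first; translations are
  zero (the toy capsid is centered at the origin by construction).
* **Toy capsomer**: 3 chains (A, B, C) of Gaussian-blob pseudo-atoms
  (σ = 2.5 Å, 8 Å chain offsets, elements drawn from C/N/O/S with
  protein-like weights), recentered so its mass center sits *exactly* at
  the requested shell radius (default 100 Å) in a generic direction. With
  the 60 matrices this yields a 60-copy, 180-chain capsid whose symmetric
  R_M is exactly the requested radius.
* **Helical lattice**: the same blob replicated onto a cylinder
  (13 protofilaments, default 3 rings, radius 115 Å, axial rise 82 Å),
  emulating microtubule geometry at the lattice level only.
* **Charged dimer**: two single-site units of opposite charge on the
  x-axis, for force-probe checks with a closed-form answer.

What the fixtures do **not** emulate: real protein shape, sequence,
chemistry, packing interfaces, or non-icosahedral capsid translations.
They exercise the geometry exactly — centers, radii, symmetry, counts —
which is what the operations act on.

## Problem sizes and verification

The shipped tests and the acceptance script run on: a 150-atom capsomer
expanded to 60 copies (9 000 atoms, 180 chains); a 39-subunit cylindrical
lattice plus a 120-atom motor blob; 100-seed rigidity sweeps of 100-atom
units. Key verified properties (see `tests/`): rigidity ≤ 10⁻⁶ Å,
quaternion-oracle agreement ≤ 10⁻⁹ Å, detachment ratios 1.4/2.0 at
relative 10⁻⁶, all-atom R_M against a brute-force sum at relative 10⁻⁹,
icosahedral group closure ≤ 10⁻⁶, preset pose counts 7/91/21/23/36/181/81,
byte-identical scan reruns, and read-back agreement with an independent
PDB parser (`gemmi`). One optional test validates against the deposited
turnip crinkle virus capsid (PDB 3ZX8) when the user supplies the file at
`data/3ZX8.pdb`; it is skipped otherwise since the entry cannot be
shipped.

## Limitations

* Rigid bodies only — no flexibility, minimization, or clash resolution.
* The symmetric R_M assumes the assembly is a single shell; for
  multi-shell or strongly aspherical assemblies use the all-atom form and
  interpret shift fractions accordingly.
* Rotations are restricted to the three coordinate planes; arbitrary-axis
  rotations require pre-aligning the structure.
* The force probe is qualitative (see above).
* PDB fixed columns cap coordinates below 10 000 Å and chain ids at one
  character; very large expansions can exceed the coordinate field.
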