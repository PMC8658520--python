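# Methods

`implantfem` simulates virtual implant therapy on a voxel-based finite-element
model of a posterior mandibular segment: a CT volume (synthetic by default) is
converted element-by-element into a heterogeneous linear-elastic bone model, a
molar is virtually extracted, one-piece implants of 3 diameters × 4 lengths are
virtually placed into the refilled socket, and each configuration is solved
under a 50 N oblique occlusal load to compare peak equivalent (von Mises)
stress in the peri-implant bone across designs.

## Model and assumptions

**Constitutive model.** CT attenuation is mapped to apparent bone density by
the linear calibration ρ = ct · 0.945 × 10⁻⁴ (ρ in gf/cc, ct in HU), and
density to Young's modulus by Keyak's piecewise law:

| density ρ (gf/cc) | E (MPa) |
|---|---|
| ρ = 0 | 0.001 |
| 0 < ρ ≤ 0.27 | 33 900 ρ²·²⁰ |
| 0.27 < ρ < 0.6 | 5507 ρ + 469 |
| 0.6 ≤ ρ | 10 200 ρ²·⁰¹ |

Bone is heterogeneous but **linear** isotropic (ν = 0.4): the density-dependent
modulus captures the internal structure, while each solve is a linear static
analysis. No plasticity, damage, or strain-rate dependence is modelled. Teeth
(E = 4.80 × 10⁴ MPa, ν = 0.23) and the titanium implant (E = 11.0 × 10⁴ MPa,
ν = 0.29) are homogeneous.

Interval boundaries follow the printed inequalities (0.27 belongs to the low
power branch, 0.6 to the high). As printed, the law is *not* globally
monotone: the high branch starts ≈3.2 % below the linear branch's end at
ρ = 0.6 (and the 0.001 MPa floor exceeds the low branch for ρ < 3.8 × 10⁻⁴).
We keep the law verbatim and treat the small boundary discontinuities as part
of the model; tests pin them below 5 %.

Negative CT values are clamped to zero density before conversion — the linear
calibration would otherwise produce negative densities for which the law is
undefined. Element density is the density of the voxel the element derives
from (each tetrahedron comes from exactly one voxel, so no further aggregation
rule is needed).

**Interface and loading.** The bone–implant interface is perfectly bonded
(shared mesh nodes), i.e. complete osseointegration; no contact or friction.
The occlusal load is a single concentrated nodal force — 50 N at 45° to the
tooth axis, directed buccally → lingually with a compressive axial
component — applied at the implant-crown node nearest a buccal-cusp target
point (2 mm buccal of the axis on the crown top). A point load is singular in
the continuum limit; peri-implant maxima are extracted from *bone* elements,
never at the loaded (implant) node, so the singularity does not contaminate
the reported metric. The inferior border of the mandibular segment is fully
clamped, implemented as the lowest lattice node plane of the mesh.

## The synthetic phantom

No CT study is bundled, so the default input is a parametric phantom: a
straight rectangular-section prism (7.8 × 10.1 × 31.6 mm at 0.39 mm voxels)
with a 1.2 mm cortical shell on the buccal, lingual, inferior and crestal
faces, a noisy trabecular interior, 23.4 mm of bone height, and one cylindrical
tooth (radius 3 mm, root 11 mm, crown 8 mm) at the future implant site. The
mesiodistal faces are cut planes and carry no shell. Per-tissue Gaussian HU
noise comes from a single seeded generator, so a phantom is a pure function of
its parameter set.

HU defaults — cortical 9000 ± 300, trabecular 1600 ± 500, teeth 11 000 —
were chosen against two constraints of the calibration above:

1. *Branch coverage*: under ρ = ct · 0.945 × 10⁻⁴, the high power branch
   needs ct ≥ 6349 HU and the linear branch ct > 2857 HU. The defaults put
   cortical bone in the high branch (ρ ≈ 0.85, E ≈ 7.4 GPa), the trabecular
   bulk in the low branch (ρ ≈ 0.15, E ≈ 0.5 GPa), and the trabecular upper
   tail (~0.5 % of voxels) in the linear branch, so a default phantom
   exercises the whole law. (Clinical HU scales would leave everything in the
   low branch under this particular calibration slope.)
2. *Stiffness contrast*: the resulting cortical:trabecular modulus ratio of
   ~14:1 matches the order reported for mandibular bone. This contrast is
   what concentrates load transfer at the stiff crestal plate around the
   implant neck; with a much softer contrast the load instead transfers
   deep at the implant apex, which is not the regime of interest.

The bone height (23.4 mm, a typical posterior mandibular body) leaves a 16 mm
implant ~6 mm of trabecular clearance above the inferior cortical plate, so
the apical stress bulb of the longest design is not artificially stiffened by
the clamped base.

What the phantom does **not** emulate: anatomical surface shape and arch
curvature, the mandibular canal, site-dependent cortical thickness, spatially
correlated trabecular architecture (noise is voxel-independent), scanner
physics (beam hardening, partial-volume blur), and clinical HU scales. Passing
trend tests on the phantom therefore demonstrate the *mechanics* of the
pipeline — load transfer shaped by geometry and stiffness contrast — not a
subject-specific prediction; absolute stress values depend on the phantom and
are only required to be physiologically plausible (0.1–50 MPa under 50 N).

## Geometry operations

**Extraction.** A tooth (a connected component of the tooth label) is
relabelled bone, and its CT values are set to the mean CT of trabecular bone
(< 6000 HU) within a 2 mm shell of the socket — the "socket automatically
refilled with bone" idealization. The crown portion above the crest is also
refilled, which keeps the background voxel count invariant; the placed
implant's supracrestal portion later claims exactly that region.

**Placement.** The implant solid is a smooth cylinder of diameter d with a
hemispherical apex, reaching depth l below the crest, plus a supracrestal
abutment/crown cylinder. Threads are omitted: the compared quantities (peak
peri-implant stress and its diameter/length trends) are set by the gross
load-bearing geometry. The crown is congruent with the extracted tooth crown
(radius 3 mm, height 8 mm) for *every* design, so the lever arm of the oblique
load is identical across the sweep — the part of the implant above the bone
margin, on which the bending moment acts, is the same in all models, mirroring
the clinical situation where the prosthetic crown does not change with the
fixture. Placement claims only bone-labelled voxels (the refilled socket and
crown), never background, making it idempotent and conservative. An apex that
would enter the inferior cortical band (default clearance 1.2 mm) is an
invalid-placement error reporting the overshoot in mm.

## Discretization and solver

Each included voxel is split into **5 tetrahedra** (four corner tets + one
central tet on the cube corners), with the mirror-image decomposition chosen
by voxel-index parity so shared faces between neighbouring voxels are
triangulated identically — the mesh conforms by construction, element volumes
sum exactly to the voxel volume, and element quality is a lattice constant.
Nodes are exact lattice points merged by integer index (the 10⁻⁹ mm tolerance
is never exercised). The default sweep mesh has ≈39 k nodes and ≈175 k
elements (≈118 k DOF).

Elements are constant-strain tetrahedra with exact one-point integration —
the canonical tet4 formulation. The global system is reduced by eliminating
clamped DOFs and solved **directly**: sparse LU with symmetric-mode minimum-
degree ordering, factored in single precision (halving time and memory) and
polished by iterative refinement against the double-precision matrix until the
relative residual is ≤ 10⁻¹⁰; a full double-precision factorization is the
automatic fallback if refinement stalls, and Jacobi-preconditioned conjugate
gradients (rtol 10⁻⁸) take over above 2 × 10⁵ free DOFs. Every solve checks
its residual and raises on under-constrained (singular) systems; equilibrium
(Σ reactions + applied load) holds to ~10⁻⁹ N on production solves, against a
10⁻⁶ N acceptance gate.

Stress is recovered per element from the constant-strain operator (no nodal
averaging — averaging conventions are solver-specific, and unaveraged maxima
are the conservative choice). Equivalent stress is the standard von Mises
invariant; principal stresses are the sorted eigenvalues of the element
tensor.

## Post-processing definitions

*Peri-implant bone* is the 1-ring: bone elements sharing at least one node
with any implant element — the simplest deterministic surface-adjacent
region. The peak is the element-wise maximum over that region (ties broken
toward the lowest element id). The peak location is tagged axially —
neck / middle / apex by equal thirds of the intrabony depth — and by side
(buccal / lingual of the implant axis).

## Determinism and reproducibility

All randomness flows from one seed in the run configuration; the phantom is a
pure function of its parameters, meshing and placement are deterministic, and
ties break by lowest index. Two runs of the same configuration produce
byte-identical summary CSVs. Per-configuration wall-clock times are therefore
reported in logs and the manifest, never in the summary table. The manifest
(config echo, versions, seed, timings, outputs) suffices to re-run a sweep
bit-identically.

## Known limitations

- Absolute stress magnitudes are phantom-specific; only trends and
  localization are claims of the package.
- Smooth (threadless) implants underestimate local thread-level stress
  concentration.
- The single-node load is mesh-dependent in a vanishing neighbourhood of the
  load point (inside the titanium, which is excluded from the metric).
- Voxel staircase surfaces create small artificial stress risers at material
  boundaries; element-wise maxima are correspondingly conservative.
- tet4 elements are stiff in bending; the cantilever verification documents
  the refinement (8 elements through the thickness) at which tip deflection
  is within 5 % of the Euler–Bernoulli value.
- The 12-design grid uses diameters {3.8, 4.3, 6.0} mm and intrabony lengths
  {9, 11, 13, 16} mm; the 4.3 mm diameter follows the consistently used value
  where a source table once misprints 2.3 mm.
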