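# Methods

`spinefield` computes how current dipoles in the spinal cord appear as
magnetic fields on a triaxial sensor array over the back, under volume
conductor models of increasing realism, and quantifies how the choice of
model changes the lead fields.  This note documents the physics, the
numerics, and the choices made where the design was genuinely open.

## Physical model

In the quasi-static regime the field at sensor position **r** splits into a
primary and a volume-current part,

    B(r) = B_p(r) + B_v(r),
    B_p(r) = (μ0/4π) Q × (r − r_Q) / |r − r_Q|³,

for a current dipole **Q** at **r_Q**.  The volume currents −σ∇φ in a
piecewise-homogeneous conductor contribute through the Geselowitz surface
integral over every conductivity interface S_i,

    B_v(r) = −(μ0/4π) Σ_i (σ_i⁻ − σ_i⁺) ∫_{S_i} φ(r′) (r − r′)/|r − r′|³ × dS′,

with σ_i⁻/σ_i⁺ the conductivities inside/outside S_i.  Only the boundary
potentials φ are needed; they satisfy a second-kind integral equation driven
by the infinite-medium dipole potential.  Tissue conductivities (S/m):
torso 0.23, heart 0.62, lungs 0.05, spinal cord 0.33, vertebral bone 0.007.
The magnetic field is invariant to a global rescaling of all conductivities
(potentials scale as 1/k, jumps as k) — a property the tests assert.

### Model hierarchy

| tag | conductor | solver |
|-----|-----------|--------|
| Inf | infinite homogeneous medium | B = B_p exactly |
| SS  | spherically symmetric, origin 1 m anterior of the source space | Sarvas closed form |
| CS  | homogeneous torso-shaped | corrected sphere (harmonic basis, ℓ ≤ 10) |
| 1c LC | torso | linear-collocation BEM |
| 3c LC | + heart, lungs | linear-collocation BEM |
| 4c LC | + spinal cord (8 mm tube) | linear-collocation BEM |
| 5c LC | + vertebral bone (16 mm tube) | linear-collocation BEM |
| 5c LCi | as 5c | BEM with isolated-source two-pass at the cord surface |

The Sarvas field depends only on the sphere origin, never on the radial
conductivity profile; radial dipoles are magnetically silent.  Placing the
origin ~1 m anterior makes the sphere surface locally approximate the back,
so inferior–superior and left–right spinal dipoles are "tangential" and
survive; pushing the origin further anterior converges on a half-space
model (tested as a monotone-convergence property).

### Corrected sphere

Only the model class (sphere perturbed by spherical-harmonic gradients of
the boundary, ℓ up to 10) is fixed by convention; the fitting procedure
here is: the correction potential of a homogeneous conductor is harmonic
inside it, so it is expanded in interior solid harmonics (r/R₀)^ℓ Y_ℓm
about the torso centroid (R₀ = mean vertex radius, for conditioning;
ℓ(ℓ+2) = 120 real basis functions at ℓmax = 10).  Coefficients follow from
a plain least-squares fit of the insulating Neumann condition at the mesh
vertices (gradients of the polynomial basis by central differences,
h = 10⁻³ mm); the fit residual for a centroid probe dipole is stored and
decreases monotonically in ℓmax.  The surface potential then feeds the same
Geselowitz integral as the BEM.  On a spherical boundary this reproduces
the closed form (RE < 0.02 at the test resolution).  With sensors ~10 mm
from the boundary the truncated basis is known to produce artefacts; this
behaviour is reproduced, not repaired, and a warning is emitted only when
sensors are inside the conductor.

### Boundary element solver

Linear (hat) basis on vertices, collocation at vertices.  For vertex v on
surface k,

    [σ_k⁺ + (σ_k⁻ − σ_k⁺) ω_v] φ_v − Σ_j (σ_j⁻ − σ_j⁺) (W_j φ)_v
        = Q·(y_v − r_Q) / (4π |y_v − r_Q|³),

where W_j is the double-layer operator of surface j and ω_v the interior
solid angle of the polyhedron at its own vertex divided by 4π.  The
right-hand side is independent of the source compartment's conductivity
(the σ_s of the infinite-medium potential cancels against the equation's
source scaling).

**Assembly.**  Each (collocation point, triangle) interaction uses the exact
van Oosterom–Strackee signed solid angle; triangles are uniformly 4-way
subdivided to a depth that grows as the point approaches (distance/diameter
bands 4, 2, 1, 0.5 → depths 1–4), and each subtriangle's solid angle is
attributed to the parent triangle's vertices by the linear shape functions
at the subtriangle centroid.  Far pairs therefore reduce to a one-point
rule and near-singular pairs are resolved geometrically.  Because
subdivision preserves total solid angles exactly, the operator's row sums
satisfy the solid-angle identity to machine precision — which is also how
the diagonal jump coefficients ω_v are obtained (triangles containing the
collocation vertex contribute exactly zero, being coplanar with it).
Flat-triangle coplanarity also means no singular integrals ever need
regularisation.

**Deflation and factorisation.**  The all-surface constant spans the null
space; a rank-one deflation (α/N added to every entry, α the mean diagonal
magnitude) makes the dense system regular.  The deflated constant is
non-physical: closed equipotential surfaces contribute no external field,
which the tests verify.  One LU factorisation is reused for all dipoles
(549 sources × 3 orientations are a single multi-RHS solve).

**Magnetic integral.**  The Geselowitz integral with the linear φ
interpolant uses the same distance-banded subdivision with a per-subtriangle
centroid rule, projected directly onto each channel's orientation.  Field
points on an integration surface raise an error.

**Isolated-source approach.**  With the cord (σ 0.33) inside bone
(σ 0.007), sources sit near a 47:1 conductivity contrast.  The isolated
variant first solves the cord as a stand-alone conductor (σ_out = 0), then
solves the full system for the correction with the residual right-hand
side.  The split is algebraically exact, so on well-separated geometry it
agrees with the direct solve to solver precision while routing the strong
local contrast through the dedicated sub-problem.

**Validation oracles.**  The solver is checked against two independent
references: a spectral solution for the surface potential of a dipole in a
homogeneous sphere (constructed numerically — closed-form infinite-medium
radial derivative projected onto Legendre functions, interior harmonics
added to satisfy the Neumann condition — rather than transcribed
coefficients), and the Sarvas closed form for the external field.  At
~2500 vertices the total field matches the closed form with RE < 0.02 for
tangential dipoles up to eccentricity 0.8, improving under refinement;
radial dipoles cancel to RE < 0.03.

## Synthetic geometry

No participant scan or registered thorax mesh is available, so the
generator emulates the study conditions deterministically (no randomness;
the config seed exists for interface completeness):

* **Torso** — superellipse cross-section (exponent 2.5; flat-ish back for
  ray casting), width 320 mm, depth 240 mm, height 700 mm with 30 mm
  rounded caps; the height includes an abdomen/neck margin so the 30 mm
  sensor grid yields ~250 sites.  Cross-section centres follow the spine's
  sagittal bow so the cord depth stays exactly 50 mm from the back.
* **Spine** — a degree-5 polynomial per coordinate: linear in x over a
  606 mm span plus a single zero-mean kyphotic bow (20 mm amplitude, well
  under the curvature that would self-intersect the tubes).  Resampling at
  10 mm arc steps gives 61 medial sources; each carries a ring of 8
  sources at 4 mm radius in the plane normal to the local tangent.  Frames
  are rotation-minimising (parallel transport), so ring orientations follow
  the curvature without flips; ring position 1 is +4 mm toward the
  subject's left, position 5 toward the right (the "left/right medial"
  pair, 8 mm apart).
* **Cord and bone** — capped tubes of radius 8 and 16 mm swept along the
  centreline, extended 1.2 radii beyond the source span; reference
  resolutions land near the study's mesh table (cord ~5160 vertices at
  density 1).
* **Heart and lungs** — ellipsoid surrogates (heart left-anterior of the
  spine; two lateral lung ellipsoids) sized to the reference vertex counts
  and verified disjoint from the bone tube and from each other.
* **Sensors** — a 30 mm grid ray-cast orthographically along +Y from a
  plane 200 mm behind the back; first hits offset 10 mm along the outward
  face normal give ~253 sites (759 channels).  Channel axes: X
  inferior–superior, Y along the outward normal (the primary, sagittal
  axis), Z completing the right-handed frame.  Sensors are point-like.

A single `density` factor in (0, 2] scales every mesh resolution linearly
in vertex count; counts are monotone in it.  The default study density is
0.5 (≈7200 BEM unknowns for the 5-compartment model), where the sphere
oracle puts the solver error well below the model differences being
measured; the full-density geometry matches the reference mesh table.

### What the generator does not emulate

Real anatomy is not rotationally symmetric: vertebrae are discrete,
non-circular and varying in size; lungs are not ellipsoids; the torso has
arms and asymmetries.  Passing tests on this geometry show that the solver
and the analysis pipeline are correct and that the bone effect is a robust
consequence of the conductivity geometry — not that any specific patient's
lead field is predicted.  Quantities tied to participant anatomy are
therefore reproduced as scaled-down targets with wide tolerances (±25% for
eigenvalue ratios, ±5–7 percentage points for pole asymmetries, ±40% for
amplitude fold ratios).

## Analyses

* **Model comparison** — for each model pair, the relative error
  RE = |a − b|/(|a| + |b|) and squared Pearson correlation of the channel
  topographies of all 61 medial sources × 3 cardinal orientations; medians
  are taken over the pooled per-source-per-orientation values (pooling
  before the median, an explicit convention).  The A–P orientation subset
  is computed but its fields are ~20× weaker than I–S and are flagged
  accordingly.
* **Orientation scan** — SVD of each source's triplet L = [l_x l_y l_z]
  (economy SVD; rows of V are source orientations; signs fixed so each
  eigenfield's largest-magnitude channel is positive).  Reported: s1/s2,
  s1/s3, the acute angle between the first orientation and the I–S axis,
  and the residual angle to the local spine tangent.  Summaries use slices
  10–50, where the array samples the topography fully.
* **Lateral separation** — RE/CC² between left and right paramedial
  sources of each slice, driven along the local spine tangent, over all
  759 channels.  The pole-asymmetry diagnostic (positive/negative field
  extrema and their percentage ratio) is read from the primary-axis (Y)
  channels — the topography as conventionally mapped; tangential-channel
  lobes are single-signed and would mask the pole effect.
* **Conductivity sweep** — s1/s2 at the T9 source as σ_bone varies: the
  attenuation of off-axis sources grows with the cord/bone contrast and
  collapses toward the bone-free level as the jump vanishes.
* **SNR planning** — N = ⌈(noise·√bandwidth / amplitude)²⌉ trials for a
  0 dB evoked average, clamped to at least 1.

The "T9" slice is the medial source at 60% of the arc from the inferior
end (slice 36 of 0–60); configurable, since the label is anatomical only.

## Numerical conventions and edge cases

* Geometry in mm; unit conversion to SI happens only inside field
  computations.  Fields are reported in fT per nAm (10⁻⁶ T per A·m).
* The classical inside-minus-outside jump convention is used in both the
  potential equation and the magnetic integral; both signs are pinned by
  the sphere oracle (radial-dipole silence and closed-form agreement)
  rather than by transcription.
* Dipoles are rejected outside the conductor and warned about within one
  vertex spacing of a boundary; ring sources sit 4 mm inside the 8 mm cord,
  so study dipoles never approach closer than 4 mm.
* SVD ties (s1 = s2) leave the ratio exactly 1; rank-0 triplets raise.
  RE of two zero vectors and CC² of constant vectors raise rather than
  return NaN.
* `run_study` manifests record SHA-256 hashes of every result table and
  lead-field matrix; identical configs reproduce identical hashes (the
  pipeline contains no stochastic stage).

## Known limitations

* Collocation weighting within a triangle is approximated by subdivided
  one-point rules rather than fully analytic linear-shape integrals; the
  sphere oracle bounds the resulting error (<2% at study resolutions), but
  very coarse meshes (density « 0.25) degrade gracefully rather than
  sharply.
* The corrected-sphere basis cannot represent sources at high eccentricity
  relative to its expansion origin (truncation at ℓ = 10), and its
  near-boundary sensor artefacts are inherent to the model class.
* Bone is a smooth constant-radius tube; anatomical vertebrae would
  modulate the attenuation along the cord rather than scale it uniformly.
* No inverse modelling, sensor noise simulation, or real-data ingestion.
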