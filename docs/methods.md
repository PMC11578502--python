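# Methods

## Problem and model

After subtalar arthrodesis the talus and calcaneus are held by an
intramedullary interlocking nail while an ~1 mm debrided articular gap
waits for bony fusion. The mechanical environment in that gap — compressive
(normal) versus shear (tangential) micromotion — is believed to decide
between fusion and non-union, and it is controlled by the bending and
torsional loading of the nail. `fusegap` implements the full analysis chain
for this problem: a parameterized finite-element model of the stabilized
hindfoot, probabilistic material sampling, stress evaluation under an
inversion/eversion load sweep, extraction of the implant section moments,
decomposition of the articular-gap displacements, and the regression of gap
micromotion against implant moments.

Because no patient geometry ships with the package, the anatomy is replaced
by a parametric **bone analog**: two rectangular blocks (calcaneal and talar
analogs) whose articular interface is a pair of concentric cylindrical
surfaces (radius `R` and `R + g`), so the gap width `g` is exact everywhere
while the gap normals vary over the joint — without that curvature the
normal/tangential split would be trivial. Each block carries a cortical
shell (2.5 mm nominal) around a cancellous core; the shell is thickened by
one standard deviation (+0.4 mm) at the articular facets and thinned at the
supported anterior faces, reflecting the reported regional variation of
hindfoot cortical thickness. A hollow titanium nail (75 mm long, Ø12 mm,
2 mm wall) crosses the gap vertically and is interlocked by three
transverse Ø3.7 mm screws (two calcaneal, one talar, bicortical). PMMA
pads on the anterior faces model the forefoot support and carry the fixed
boundary; a reference point 17 mm below the heel, kinematically coupled to
the posterior plantar surface with a single free rotation about the
transverse axis, models the soft-tissue pivot of the heel. The vertical
650 N stance force acts through a rigid coupling on the proximal talar
surface; hindfoot tilt φ ∈ [−20°, +10°] (inversion negative) is modeled by
rotating the force vector about the anterior–posterior axis, which is
equivalent to tilting the foot but avoids remeshing. Axes: x anterior,
y vertical (distal→proximal), z transverse; units mm / N / MPa.

The analysis pipeline, not the anatomy, is the contribution: all
postprocessing operators (section moments, gap decomposition) also accept
externally produced VTU displacement/stress fields.

## Discretization and solver

All bodies are meshed with straight-sided 10-node tetrahedra (quadratic
displacement, 4-point Gauss rule, exact for the stiffness integrand of
straight elements). Structured generators are used throughout: a Kuhn
6-tet split of box grids for the blocks and pads (conforming, including
the pad/bone interface, which shares nodes), a cylindrical-coordinate grid
for the nail, and extruded disk fans for the screws. Midside nodes sit at
edge midpoints. The reference element size is 1.44 mm; probabilistic
sweeps run at 5 mm (see *Problem sizes*). Because the cortical shell is
classified per element centroid, the shell thickness is floored at one
element layer on coarse meshes — a shell that vanished with coarsening
would change the load path qualitatively rather than just numerically.

Kinematic couplings are eliminated exactly: coupled surface nodes move as
`u = t + θ × d` of their reference point, and the system is reduced with a
sparse transformation before factorization (SuperLU). The locking screws
are embedded by stiff penalty springs (default `100 E_max h`) that tie
every screw node to the displacement field of the body that physically
surrounds it: the nail inside the wall annulus, bone outside the nail,
nothing inside the hollow bore. This makes the screws the only load path
between nail and bone, which is what produces the screw-local jumps in the
section-moment curves. The nail bore through the bone is not carved; the
overlapping cancellous material (E ≈ 100 MPa against titanium's 110 GPa)
adds a negligible parallel stiffness, and a bore-contact pair would never
engage at the ≤0.2 mm motions of interest.

Articular contact is node-to-surface penalty contact with Coulomb friction
(μ = 0.3, normal penalty `100 E_max / h` per unit area, tangential a tenth
of that), resolved by an active-set iteration with a stick/slip update.
The pairing is computed on the undeformed configuration and gaps are
updated linearly in `u` — consistent with the small-strain kinematics and
with gap changes two orders of magnitude below the gap width. In the
arthrodesis sweeps the ~1 mm gap never closes, so the stiffness
factorization of each material sample is reused across all seven angles;
the contact machinery is exercised by the `contact_blocks` verification
fixture (pressure transmitted across a closing gap to equilibrium
accuracy, tangential reactions capped at μN). Because tie and contact
penalties scale with the largest sampled modulus, scaling every modulus by
k scales displacements by 1/k and leaves stresses and contact states
exactly invariant.

Stress output is the element average of the integration-point stresses
(equal to the centroid value on straight elements); all reported regional
maxima use this convention, which is robust next to contact and tie
regions. Nodal extrapolation is deliberately not used for maxima.

## Probabilistic sampling

The four phases are homogeneous, isotropic, linear-elastic with normally
distributed Young's moduli: cortical 17000 (3400) MPa, cancellous 100 (20),
titanium 110000 (4400), PMMA 3000 (300); the artificial-bone table replaces
the bone phases with 16350 (1635) and 155 (16). Poisson ratios are fixed
(0.3, PMMA 0.4). Latin hypercube sampling draws one value per
equal-probability stratum per parameter (random within the stratum,
seeded); draws are clamped to `max(E, E_mean − 3 SD)` and strictly positive,
since a 20% CoV normal model admits nonphysical negative stiffness.
Parameters are sampled independently (no correlation model).

## Section moments

The implant frame puts x along the nail's dominant principal axis
(volume-weighted centroid PCA), oriented from the calcaneal entry to the
talar end; z is the projection of the global transverse axis onto the cut
plane and y completes the right-handed triad. With the nail vertical this
makes Mx the torsion, My the sideways and Mz the forward bending moment.
At each axial station (1 mm default spacing) the cut plane is intersected
with every straddling tetrahedron of the nail *and* screws (screws crossing
a cut carry load); tractions `t = σ·n` are integrated over the resulting
polygons with a degree-2 edge-midpoint triangle rule, evaluating σ from the
displacement field at the quadrature points so the through-wall bending
gradient is captured. Stations are nudged by 1e-6·span off exact vertex
coincidences. The "joint gap" station is where the gap mid-surface crosses
the nail axis. Free-body equilibrium against the known external loads is
the acceptance oracle for this operator (≤5% at every station on the
cantilever-tube fixture, exact for tip torque).

## Gap kinematics

Every node of the lower (calcaneal) articular surface is paired with its
closest point on the upper (talar) surface by exact point-to-triangle
projection; a KD-tree over triangle centroids prunes candidates, and the
candidate set is then widened to all triangles within
(best distance + max triangle circumradius), so the result is provably
identical to the exhaustive scan (ties go to the lowest triangle id). The
surface normal at the projection is the facet normal for interior
projections, the mean of the two adjacent facet normals on an edge, and
the angle-weighted vertex normal at a vertex; normals point from the upper
body toward the lower one. The relative displacement `Δu = u_lower −
u_upper` (upper side interpolated with the quadratic facet functions) is
split as `Δu_n = Δu·n` (negative = gap closing) and `Δu_t = Δu − Δu_n n`;
the signed tangential scalar projects `Δu_t` on the anterior direction
mapped into the tangent plane (configurable). The decomposition is
computed on the undeformed pairing — displacements are ≲0.2 mm against a
1 mm gap — and the nearest-point map is not symmetric between the two
surfaces, which is inherent to closest-point pairings and not asserted.
Monitor points maximize the |eversion − inversion| discrepancy of one
component over a labeled facet subregion (posterior by default), ties to
the lowest point index.

## Statistics

Per-angle means and sample SDs (n−1) summarize each quantity over the LHS
samples; report bands are ±1 SD. The displacement–moment regressions are
ordinary least squares of the per-angle *mean* monitor displacement on the
per-angle *mean* gap-station moment (tangential vs torsion Mx, normal vs
sideways bending My) with R² = 1 − SS_res/SS_tot (defined 0 for a constant
response); fitting on means matches comparing mean section moments near
the joint gap, and per-sample fits remain available through the collected
tables. Material influence is ranked by standardized (z-scored) multiple
regression coefficients of the per-sample monitor displacements on the
four sampled moduli; collinearity is flagged via the design condition
number. Real and artificial bone are compared as the mean over angles of
|real − artificial| / |real| of the per-angle means.

## What the synthetic study does and does not show

The generator emulates the *structure* of the problem — biphasic bones, a
curved debrided gap, an interlocked nail, eccentric tilting stance loads,
anterior support and heel pivot — but not the anatomy: there are no real
facet shapes, no per-patient cortical maps, no soft tissues, and the screw
count/positions are idealized. Consequently the pipeline reproduces the
*qualitative* mechanics (torsion reversal between inversion and eversion
with a near-zero neutral torsion by mirror symmetry; near-constant forward
bending; linear displacement–moment relations with R² ≥ 0.99; minimal gap
micromotion in neutral stance; cortical modulus dominating both gap
displacement components) while its absolute stresses and displacements
differ from any patient geometry. Passing tests therefore validate the
operators and the study logic, not patient-specific magnitudes.

## Problem sizes and numerical choices

Probabilistic sweeps and the acceptance study run at a 5 mm element size
(≈19k nodes, 56k dof, ≈15 s per sample including one factorization plus
seven angle solves), 10 LHS samples per material configuration and seven
angles; verification fixtures use ≤2 mm elements as their tolerances
require. These sizes were chosen so a full study completes in minutes on
one CPU while every acceptance property holds with margin; all sizes are
configuration options. Key tolerances: solver residual 1e-9 relative,
decomposition reconstruction 1e-10 mm, statics residual 5%, beam deflection
5% against Timoshenko theory (Cowper shear coefficient). Seeds: the
pipeline derives per-configuration LHS seeds as `seed + 1000·k` over the
material kinds; identical configurations and seeds give byte-identical CSV
outputs.

## Known limitations

Small strains and linear elasticity only (contact is the sole
nonlinearity); no cyclic loading, fatigue, bone remodeling or
screw-loosening; tied (not frictional) bone–screw interfaces; structured
meshes imply a slightly chiral tet splitting whose mirror-asymmetry error
is visible in the near-zero neutral torsion; the analog's regions of
interest approximate, not reproduce, the anatomical facets.
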