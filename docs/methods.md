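# Methods

This note records the models, numerical choices and limitations behind
`endotwin`, at the level of detail a user needs to judge what a passing test
suite does and does not demonstrate.

## Units

Millimetres, seconds, Newtons, MPa (= N/mm²) and tonnes, so that
1 N = 1 tonne·mm/s² without conversion factors. Densities given in g/cm³ in
configuration files are converted to tonne/mm³ (1 g/cm³ = 10⁻⁹ tonne/mm³).

## Catheter beam model

The catheter is a chain of two-node elements with 6 DOF per node (position +
orientation quaternion). Element behavior is corotational: a per-element
frame is built from the current node positions (x-axis along the element)
and the slerp-averaged node rotations (which fixes the roll/twist), local
deformations are measured against it, and a shear-deformable (Timoshenko)
12×12 stiffness maps them to forces. The local stiffness uses the
interdependent-interpolation form with shear parameter
Φ = 12EI/(κGAL²), κ = 6(1+ν)/(7+6ν) for a circular section, which is free of
shear locking and nodally exact for slender cantilevers — the basis of the
1%-tolerance comparison against FL³/(3EI).

Defaults reflect the reference instrument configuration: length 800 mm,
outer diameter 1.32 mm (solid circular section, I = πd⁴/64; a hollow-tube
option exists), 50 nodes, Young's modulus 600 GPa, density 1.55 g/cm³.
The modulus is an effective, stability-tuned stiffness, not a physical
material constant; the printed source unit for the density (g/mm³) is
treated as a typo for g/cm³, since the alternative is 1550× water for a
polymer catheter. Gravity is off by default (transverse gravity forces are
negligible for this instrument at these speeds) and can be enabled.

Inertia is lumped: half of each element's mass ρAL to each end node, and an
isotropic rotary inertia ρ(L/2)(J + AL²/12) per node — the AL²/12 term keeps
rotational DOFs well conditioned at coarse discretizations. Mass lumping
preserves total mass and momentum exactly (the free-body test asserts
impulse = momentum to machine precision).

Time integration is backward Euler with one linearization per step:
(M + dtC + dt²K)v⁺ = Mv + dt(F − f_int), C = αM + βK (α = 0.1 s⁻¹,
β = 0.01 s). The approximate tangent ΛK_localΛᵀ ignores the variation of the
element frame; it is symmetric positive semidefinite, which keeps the
implicit system SPD and the step unconditionally stable. The cost is linear
(not quadratic) convergence of the static Newton loop; the static solver
therefore stops either on the force residual (10⁻⁸ relative by default) or
when the increment reaches the rounding floor of the rotation extraction
(~10⁻¹⁰ mm).

The insertion driver is a moving clamp: the base node's position is
prescribed to start + speed·t·axis and its orientation held at the rest
frame. The full 50-node catheter is always simulated (no progressive
node deployment); this keeps the node count fixed at the reference
configuration at the price of simulating the not-yet-inserted portion.

## Contact

Detection is point (catheter node) versus triangle (lumen surface) with two
thresholds: alarm distance 2.0 mm (candidate) and contact distance 0.66 mm =
catheter radius (active). Those defaults are package choices — the
parameters are standard but their values are scene-configurable and logged.
Closest points use the Voronoi-region (Ericson) algorithm, vectorized over
pairs; a broad phase prefilters with alarm-inflated triangle bounding boxes
(a strict superset of true hits, so it cannot change results — the test
oracle is the exhaustive scan). Per node, pairs dominated by an adjacent
triangle that is strictly closer (ties broken toward the lower triangle
index) are collapsed, so an edge or vertex hit yields one pair.

Resolution is a velocity-level projected Gauss–Seidel over per-contact
impulses: the normal impulse is projected to ≥ 0 with a positional
stabilization bias that removes any penetration beyond the contact distance
within the step, and the two tangential impulses are projected onto the box
|λ_t| ≤ μλ_n (a 4-direction polyhedral Coulomb cone) with μ = 0.62, a single
kinetic = static coefficient. The Delassus operator is formed exactly
through the factored implicit system (one linear solve per contact row), so
the contact coupling is monolithic with the beam (and FEM) dynamics.
Convergence is declared when the largest impulse update in a sweep, divided
by dt, falls below 10⁻⁶ N (max 200 sweeps); non-convergence is a warning
carrying the residual, and the best iterate is used — on stiff multi-contact
configurations the remaining residual is typically 10⁻⁵–10⁻⁴ N against
contact forces of 0.1–2 N.

Two consequences of the stabilization bias are worth knowing. First, a
contact detected *below* the contact distance receives a corrective normal
impulse, so its reported normal force transiently exceeds the externally
applied load (and with it the friction bound); at steady state the gap sits
at the contact distance and forces are exact. The stick/slip transition is
therefore asserted on resting contacts. Second, a candidate pair above the
contact distance is allowed to approach only down to the contact distance
within one step, which prevents tunneling at the simulated speeds.

## Vessel FEM

Linear (P1) tetrahedra throughout. The elastic variant is corotational: the
rotation is extracted from the deformation gradient by SVD-based polar
decomposition per element, and the constant small-strain stiffness acts in
the rotated frame. A `pure_linear` switch disables rotation extraction for
strict linearity checks. The corotational variant is the default reading of
"elastic" because the wall visibly rotates at millimetre-scale
displacements; pure linear FEM would misrepresent it.

Hyperelastic variants use the energies W listed in the README with two
additions required by displacement-only FEM: a −c·ln J consistency term with
c chosen so the stress vanishes in the reference configuration
(c = 2C₁₀, 2C₁₀ + 4C₀₁, Σ2μᵢ/αᵢ respectively), and a volumetric penalty
κ(J−1)² with κ = 100 × the model's small-strain shear modulus
(μ = 2C₁₀, 2(C₁₀+C₀₁), Σμᵢ) — strict incompressibility (I₃ = 1) is
numerically singular, and the penalty linearizes to a Lamé λ = 2κ, which is
how the "matched moduli" comparisons against linear elasticity are built.
All three energies are non-negative and vanish only at rest for positive
coefficients. Stresses are analytic (Ogden via eigendecomposition of C);
tangents are analytic for neo-Hookean and Mooney–Rivlin and a symmetrized
central difference of the analytic stress for Ogden (step 10⁻⁶, giving
~10⁻⁹ relative agreement with the directional derivative of the assembled
force). Assembly is vectorized over elements.

Static solves use full Newton with a backtracking line search and load
ramping (4 increments for corotational/hyperelastic, 1 for pure linear),
converging to ‖f_int − f_ext‖ ≤ 10⁻⁶‖f_ext‖. Dynamic stepping instead
reuses a single per-step linearized tangent — deliberately, because that
per-timestep linearization is precisely the approximation whose accuracy
cost for hyperelastic walls the environment exists to study; both paths are
exposed.

Mesh input accepts Gmsh MSH (v2.2 and v4.1) and legacy ASCII VTK volume
meshes, STL/OBJ surfaces (via trimesh), or a watertight surface that is
filled by Delaunay tetrahedralization filtered by a generalized
winding-number containment test — adequate for chunky solids, not thin
shells, which the phantom generator meshes directly. Inverted tets are
fixed by node swap at build; a degenerate element is a hard error naming
the tet.

## Phantom generation

Vessel lumens are swept tubes: parallel-transport frames along a centerline,
rings of vertices at the radius profile, quad-split side triangles and two
cap fans (watertight). The wall is the radial extrusion of the side surface
by the 2 mm wall thickness, each prism split into three tets with the
smallest-global-index diagonal rule, which makes adjacent prisms conforming.
Inlet/outlet vertex rings are clamped, emulating the phantom's mounting; the
synthetic wall is consequently more compliant than a phantom embedded in a
support box, so static landmark displacements are meaningful relatively
(ratios, monotonicity), not absolutely.

The aorto-iliac preset is a single curved aorta-to-left-iliac path — iliac
calibre 9 mm diameter at the entrance, widening toward the aortic end, with
an optional Gaussian aneurysm bulge — rather than a Y junction: the
insertion path from the left iliac to the distal aorta is one continuous
lumen and is all the simulated protocols touch. The default surface budget
(30 rings × 16 around ≈ 480 vertices / 960 faces) matches the reference
region-of-interest mesh scale. Landmarks are inner-wall vertices on the
inner-curvature side of the mid-iliac segment; six fiducial beads sit on the
inflated bounding-box corners, rigidly attached to the mesh frame.

Synthetic tensile curves sample a ground-truth constitutive model on
λ ∈ [1, 6.5] (rupture near 550% strain, with margin) at 200 points with
seeded Gaussian noise, σ = 0.04 MPa by default — the residual scale of the
best reference fit. What the passing fits demonstrate is therefore
self-consistency (generator recovery, honest confidence intervals), not
agreement with any physical specimen: real tensile data enters through the
same CSV interface.

## Fitting

Bounded trust-region least squares with fixed initial guesses (all moduli
0.1 MPa, Ogden α₁ = 2) and bounds (coefficients ≥ 0, α₁ ∈ [0.1, 10]), so
fits are deterministic. R² = 1 − SS_res/SS_tot on stresses; RMSE on stress
residuals; 95% CIs from the linearized covariance (J'J)⁻¹s² with a
t-quantile. Monte-Carlo coverage of the generator coefficients at the
default noise is 93–96% per model — consistent with the nominal 95% given
the mild nonlinearity.

One deliberate inconsistency is preserved: the Ogden *uniaxial fitting*
formula σ = μ₁(λ^α₁ − λ^(−α₁/2)) is not λ∂W/∂λ of the Ogden energy used by
the FEM (they differ by a factor 2/α₁). The fitted coefficients belong to
the fitting formula and are only meaningful with it; the energy is used as
written for FEM. Reconciling them would silently change one or the other.
Relatedly, whether the tensile stresses are Cauchy or engineering is not
specified by the formulas' provenance; they are implemented as printed.

## Metrics

Kabsch SVD registration with a reflection guard and a collinearity check;
RMSD reported after the fit. Tip error pairs samples by timestamps when both
paths carry them, else by normalized arclength with linear interpolation.
The Fréchet distance is the discrete variant (O(nm) dynamic program); the
test oracle is the memoization-free recursive definition at small sizes.
Bézier smoothing is clamped least squares with the sample parameters
optimized by variable projection from chord-length initial values, so exact
Bézier data reproduces its control points; degree 3 by default. A 2-D
projection mode (zeroing one coordinate) mimics single-plane fluoroscopic
comparison; 3-D is the default.

## Scene runner

One implicit solve per frame: beam and (if deformable) vessel systems are
assembled and factored, contacts are detected at the current configuration,
and the PGS couples the blocks through the combined Delassus operator
(monolithic). A staggered mode — contacts against the catheter only,
reactions applied to the wall next frame — exists for debugging. Default
dt = 1 ms (aligning logs with a 1 kHz load-cell cadence), output at 100 Hz;
protocol benchmarks in the tests use dt = 2 ms and smaller phantoms to keep
the suite fast, with the dt-halving consistency test bounding the
discretization effect on the force channel at 5% RMS. Catheter placement
puts the tip at the lumen entrance pointing along the insertion axis; end
caps are excluded from collision geometry (the instrument enters through
them). All solvers are deterministic — identical scene and seed give
bitwise-identical logs; the seed feeds only synthetic-data noise.

## Known limitations

- No guidewire/catheter coaxial mechanics, torque-from-base steering,
  progressive deployment, self-contact, adhesion or rolling friction.
- No fluid–structure interaction, pulsatile loading, anisotropic or
  viscoelastic wall models.
- The corotational beam tangent is approximate (linear convergence near
  equilibria); the contact solver can leave ~10⁻⁴ N residuals on stiff
  multi-contact states (reported as warnings).
- Synthetic phantoms reproduce quantified properties of the reference
  anatomy (calibre, wall thickness, mesh budget), not its geometry; absolute
  displacement magnitudes depend on the synthetic boundary conditions.
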