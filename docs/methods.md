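# Methods

## Physical model and discretization

The quasi-static EEG forward problem is solved in the charge-based BEM
formulation: the unknown is the surface charge density induced at every
conductivity discontinuity, not the surface potential.  The governing
second-kind integral equation (potential continuity is automatic; normal
current continuity yields the equation) is collocated at facet centroids
with piecewise-constant density.  The solver works throughout in the
scaled density ρ/ε₀ (units V/m): the vacuum permittivity cancels from
every observable, and carrying it would only push the unknowns to the
1e-12 scale for no physical gain.

The summed quantity per facet is the total facet charge ρ_m·A_m: facet
areas weight the n-body sum, consistent with the refinement cost
function being the total charge magnitude per triangle.

**Near-field integration.**  Centroid point kernels are wrong for close
facet pairs and divergent for adjacent ones.  For pairs closer than
`near_factor` (default 3) local mesh lengths — mesh length defined as
the edge of the equal-area equilateral triangle, √(4A/√3) — the point
kernel is replaced by the exact integral of a uniform charge layer over
the flat source triangle (edge-decomposition closed forms for ∫1/R dS
and its gradient, with the van Oosterom–Strackee solid angle for the
normal part).  The same upgrade applies to potential evaluation, which
makes skin-facet centroids legal evaluation points (their own facet's
contribution is the exact, finite self-integral).  The self facet in the
*operator* is excluded entirely: the analytic ρ/2 jump term is its exact
contribution, and no further diagonal correction is applied.

**Deflation and charge conservation.**  On a closed insulated outer
interface (contrast K = 1 against air) the continuous operator
annihilates a constant charge layer — physically, a net monopole charge
is a valid electrostatic solution excluded only by charge conservation.
Discretely the corresponding mean equations are also *inconsistent* at
the quadrature-error level, so tolerance-level residuals and exact
neutrality cannot both hold in the raw system.  The solver therefore
deflates the per-interface area-weighted mean modes (the operator is
restricted to the neutral subspace; mean modes pass through as
identity) and reports the residual of that deflated system.  Solutions
carry exactly zero net charge on every interface, which is the correct
continuum property (each closed interface encloses zero net current
source).

**Linear algebra.**  Two interchangeable n-body backends implement the
far-field sums: a chunked pure-numpy direct sum (reference) and a
numba-compiled direct sum (default; identical to the reference to
~1e-13 relative).  An external FMM library can be registered at runtime
against the same three-primitive contract.  Systems up to 4500 facets
are assembled densely and LU-factorized (also enabling the adjoint
lead-field method below); larger systems use matrix-free GMRES
(restart 200, relative tolerance 1e-6 by default, zero or prolonged
initial guess, fully deterministic).

## Head phantoms

Nested icospheres replace MRI-derived surfaces.  The 5-layer phantom
(skin, skull, CSF, grey matter, white matter) defaults to radii
92/86/80/78/70 mm: the 2 mm CSF–GM gap reproduces the thin intracortical
gaps of real heads that drive the need for adaptive refinement.  The
3-layer phantom (SKIN, SKULL, BRAIN) reuses the outer three radii.  Air
outside the skin has conductivity exactly 0 (K = 1).  Six conductivity
presets ship as editable YAML; forward/inverse pairings (7-compartment
set with its 3-layer reduction) are enforced, never mixed.  The optional
extra interior compartment (cerebellum/ventricle analog) is recorded in
the preset file but off by default — far from the electrodes, it is
electrically almost irrelevant for EEG.

Icosphere facets are quasi-uniform: the area coefficient of variation is
bounded (< 0.09) and saturates with subdivision level rather than
decreasing — midpoint projection distortion converges to a fixed
pattern.  Mesh refinement by 4-way midpoint subdivision is *planar*
(children lie in the parent's plane, area conserved exactly) and may
leave hanging vertices; facet collocation does not require conformity.

**Resolution floor.**  Because planar subdivision never improves the
polyhedral geometry, the base mesh must resolve the geometry before AMR
can help: at 320 facets per shell the chordal sag (~2.5 mm at r = 90 mm)
exceeds the CSF–GM gap and refinement converges to the *polyhedron's*
solution, away from the sphere's.  At 1280 facets per shell the sag is
~0.6 mm and AMR behaves as intended (measured by the oracle comparisons
in the acceptance tests).  Study defaults therefore use 1280 facets per
shell for the forward phantom.  The inverse phantom needs one level more
on its high-contrast interfaces: with skull and inner contrasts near
|K| ≈ 0.96, an inverse model at the forward's resolution has solver
error that *cancels* against the non-AMR forward's (same solver, same
resolution), flattering the un-refined condition; the default inverse
resolution is therefore (1280, 5120, 5120) facets for SKIN/SKULL/BRAIN,
the phantom analog of the well-converged decimated surfaces used by
practical inverse toolchains.

**"Subjects".**  Inter-subject variability is emulated by seeded
geometry jitter: a common ±2 % scale factor, per-shell radius jitter up
to 15 % and center offsets up to 25 % of the smaller adjacent gap.
Bounding jitter by the local gap (rather than a fixed millimeter
budget) guarantees strict nesting by construction for any seed.  All
randomness flows from the single config seed through one generator;
reports are bit-reproducible.

What the phantoms do *not* emulate: non-spherical anatomy (sulci, skull
holes, anisotropic white matter), electrode-skin coupling, measurement
noise, and multi-source activity.  Passing tests therefore demonstrate
the numerical correctness and internal consistency of the method at
realistic conductivities, layer spacings and montage density — not
absolute localization accuracy on real heads.

## Adaptive mesh refinement

Cost per facet C_m = |ρ_m|·A_m; the top 1 % of refinable facets (pooled
across interfaces; a per-interface mode exists) are subdivided each
step; the skin interface — the observation region — is never refined,
so electrode facet assignments remain valid.  Stopping: relative
2-norm change of the electrode-voltage vector below 1 %, with the first
ratio comparing the first refined solve to the un-refined one; hard cap
`max_steps` = 15 with a truncation warning.  Re-solves are warm-started
by prolonging the parent density onto its four equal-area children
(charge-conserving), and the sparse near-field correction is rebuilt
incrementally — entries between facets untouched by the step are copied,
only pairs involving new children are integrated.  Costs are computed
from the fully re-converged solution at each step.

## Electrodes

256 positions from a golden-angle (Fibonacci) spiral over the upper
spherical cap covering 65 % of the sphere — near-uniform scalp coverage
with the face/neck left bare, replacing landmark-based placement that a
phantom cannot support.  Each direction is assigned to the skin facet
maximizing direction·centroid alignment (deterministic; lowest index on
ties), and voltages are the potentials at assigned facet centroids.
Voltage reference is infinity by default; average reference is provided.

## Inverse fitting

Single-dipole fits minimize residual variance with the moment solved by
linear least squares at each candidate position.  Two seeding
strategies, mirroring standard practice: refinement from the true
position (available in simulation) and a 5-mm Cartesian grid search
over the skull interior followed by refinement; when both run, the
smaller-RV result is reported.  Refinement is Nelder–Mead over position
(termination: simplex size < 0.1 mm and RV change < 1e-9; max 2000
evaluations; positions escaping the BRAIN region are penalized with
RV = 2, and a degenerate escape falls back to the seed).  Containment
tests use the inscribed sphere of the relevant interface — exact for
concentric phantoms, slightly conservative for jittered ones.

Lead fields are computed with the charge-based solver *without* AMR, as
in practical inverse toolchains.  The engine precomputes, per inverse
model, the dense LU factors and the E adjoint (transpose-system)
solutions, one per electrode; a lead field at any position then costs
two primary-field evaluations and one small matrix product (~1 ms
instead of three BEM solves), which is what makes dense grid searches
and simplex refinement tractable.

## Study design

Axes: 4 canonical dipole placements × 3 conductivity families × N seeded
phantom variants, each solved with and without AMR on the 5-layer
phantom and fitted with the matched 3-layer model.  The placements
preserve the depth/orientation contrasts of classic test batteries
while all obeying the mid-cortical rule (halfway between the GM and WM
interfaces, moment set by the nearest GM facet normal): superior
tangential, superior radial, lateral mid-height tangential, and
inferior radial.  On a concentric phantom "depth" is realized as the
direction's distance from the electrode cap — the inferior source sits
below the cap edge, the montage's analog of a deep medial source —
because radial depth variation would break the mid-cortical placement
rule that all sources share.  Dipole magnitude defaults to 20 nA·m (a typical effective cortical
source strength; all outputs are linear in it).  Default problem sizes:
1280 facets per shell forward, (1280, 5120, 5120) inverse, 256
electrodes, solver tolerance 1e-4 (two orders below the 1 % AMR stopping
threshold), 5 variants for the full study and 1–2 for the smoke and
acceptance runs.

## Analytic oracle

The N-shell concentric-sphere potential is evaluated per spherical-
harmonic degree with scaled radial bases (r/R_out)ⁿ and (R_in/r)ⁿ⁺¹ per
region, eliminating overflow to degree 200 and beyond.  The dipole may
sit in any region (both radial branches of the primary expansion are
matched), the moment is decomposed into radial (m = 0) and tangential
(m = 1, Condon–Shortley convention) parts after rotating the source to
the z-axis, and evaluation points may lie in the outer shell or in the
air continuation.  The series stops when the last term falls below
1e-10 of the running sum; if it has not reached 1e-8 by `n_terms`
(default 200) a truncation error is raised rather than returning an
under-converged value.  The degree-0 term is omitted — it contributes
only a spatially constant offset interior to the source radius.

## Numerical edge cases

Degenerate (zero-area) facets raise with the facet index; flipped
meshes are re-oriented on load (positive signed volume = outward);
point-in-surface tests use the generalized winding number, robust for
any closed oriented mesh.  Selection ties in the AMR ranking and in the
grid search resolve to the lowest index / lexicographically smallest
grid point.  Self-distance pairs in n-body sums are skipped exactly
(r = 0), never regularized.

## Known limitations

Direct O(M²) summation bounds practical meshes to a few times 10⁴
facets per solve on one core; the backend contract accepts an external
FMM for larger models.  Planar refinement cannot reduce geometric
(polyhedral) error, only charge-resolution error — hence the resolution
floor above.  The inverse model reuses the same charge-based solver
rather than an independent potential-based BEM, so formulation-
difference effects between the two BEM families are outside this
package's scope.  Angle errors are reported unfolded (0–180°);
antiparallel fits count as 180°, not 0°.
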