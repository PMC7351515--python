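# Methods

## Model structure

Skeletal muscle is treated as two mechanically linked domains occupying
the same space: an activatable intracellular domain (myofiber mesh) and
the collagen-reinforced extracellular matrix (ECM mesh).  Both are
meshes of 8-node trilinear hexahedra with 2×2×2 Gauss quadrature in a
static, total-Lagrangian large-deformation formulation.  The meshes
share nodes only at the myotendinous junction planes, where a single
node is common to the ECM, myofiber and aponeurosis elements; every
interior fiber-mesh node is paired with a coincident matrix-mesh node by
a zero-initial-length uniaxial spring of high stiffness (the
trans-sarcolemmal attachments).  With the default 3-in-series ×
16-in-parallel topology this yields 34 links on each of the two slice
faces.  Single layers of Mooney–Rivlin aponeurosis elements close the
belly proximally and distally, their thickness growing (factor 3)
toward the tendon ends, where a short free "tendon arm" element carries
the grip so that boundary conditions are not applied directly at a
myotendinous junction.

A local orthonormal frame (cross-fiber, fiber, thickness) is attached to
every muscle element; the fiber axis follows the element's
aponeurosis-to-aponeurosis edges.  ECM stress is evaluated in this
frame; myofiber stress acts along the fiber axis exclusively.

## Constitutive choices

* **ECM.** The printed anisotropic energy `k(exp(a ε) − a ε)` is used
  as-is for the normal components (asymmetric tension/compression).  For
  shear the energy is taken even in the shear strain so the shear
  *stress* is an odd function, matching the stated symmetric shear
  behaviour; the literal negative-branch formula would instead produce a
  sign-insensitive shear stress, which we consider a typographical
  artifact.  Off-diagonal stress components are reported as derivatives
  with respect to the single independent shear component; the assembly
  halves them to form the tensor contracted with the full strain
  variation, keeping forces exactly equal to energy gradients.
* **Volume penalty.** `I3` (the determinant of the right Cauchy–Green
  tensor) is penalized directly, as the published weights were tuned
  against that convention.  The element-mean fluid term couples the
  Gauss points of an element; the implementation differentiates the
  coupled element energy exactly, so the penalty force is also an exact
  energy gradient.  The weighted mean uses the reference quadrature
  volumes.
* **Myofiber stress measure.** The active + titin stress is defined as a
  Cauchy stress along the current fiber direction.  For assembly it is
  pulled back to a local second Piola–Kirchhoff component by dividing by
  the squared fiber stretch `2ε22 + 1`, taking the volume ratio as
  unity (the coincident ECM element's penalty keeps the tissue within a
  few tenths of a percent of isochoric).  Including the volume-ratio
  factor would make the fiber stress depend on the full strain state and
  cease to be the gradient of any scalar energy, destroying the
  force–energy consistency that the verification suite relies on; the
  alternative of using the Cauchy value directly as PK2 is available as
  `stress_measure = "pk2_direct"`.
* **Titin clamp.** The fitted titin parabola is slightly negative at
  zero strain (`t3 = −0.002`).  Evaluated literally, this pre-stresses
  the reference state and the passive isometric muscle equilibrates at a
  small nonzero strain (~3·10⁻⁴), contradicting the definition of zero
  strain as the undeformed, stress-free sarcomere state.  The default
  therefore clamps titin at zero (it engages at ε22 ≈ 0.046); the
  literal fit is available via `clamp_titin_nonnegative = false`.  The
  fiber energy primitive is integrated by 24-point Gauss–Legendre
  quadrature split at the clamp root, keeping the force-equals-gradient
  property to ~10⁻¹⁰ despite the kink.
* **Aponeurosis constants.** The Mooney–Rivlin constants of the original
  implementation are not published.  Defaults `a10 = 14.4`,
  `a01 = 3.6`, `ν = 0.3` give a small-strain Young modulus
  `4(a10+a01)(1+ν) ≈ 94` normalized units — about 52× the passive
  muscle fiber-direction tangent `k·a22² = 1.8` — so the aponeuroses
  are stiff force-transmitting sheets while remaining numerically
  benign.  No quantitative result asserted by the tests depends on the
  exact values beyond this stiffness ratio.

## Geometry

The true muscle contour is not published, so the geometry is a
parameterized unipennate slice: straight-to-gently-curved aponeurosis
lines (polynomials through user-supplied control points), fascicles as
straight chains between them with a distal pennation offset, one element
through the 2 mm slice thickness.  The default proportions were derived
from a kinematic force-balance argument rather than curve fitting: for
the published behaviour to be reproducible, (a) passive distal
lengthening must transfer substantially into fascicle stretch, and
(b) maximal isometric activation must allow mean fascicle shortening of
order 10% while the tendon ends are fixed, which at pennation angle θ
requires `sin²θ` gearing of the belly-thinning mode of order
`0.1/sin²θ` ≲ feasible thinning.  Both conditions meet at a strongly
pennate architecture; the defaults use a 5.0 mm pennation offset over a
~3.9 mm belly depth (θ ≈ 38°, fascicle length ≈ 6.4 mm ≈ L/4.5) with
0.12 mm (belly) to 0.36 mm (tendon-end) aponeurosis sheets.  With these
choices the isolated muscle shows uniform-direction strain fields:
identically zero in the passive isometric case, all-positive under
lengthening, and all-negative with ≈ 12% mean magnitude under maximal
isometric activation.  Exact strain percentages of the connected
variants depend on this approximate contour and are treated as
qualitative (sign and ordering) rather than quantitative targets.

## Solver

Newton–Raphson with a force-based convergence criterion: the residual
norm on free DOFs must fall below 0.5% of the internal-force norm
(floored at one force unit for unloaded states).  After meeting the
criterion, iterations continue toward a 10⁻¹⁰ relative residual while
they keep making progress, so converged states are effectively exact
equilibria — this is why the passive isometric reference reports strains
at machine precision rather than at the 0.5% force level.  Displacement
phases are applied in 4 equal increments and activation in 10 equal
`b3` increments (both configurable); non-convergent steps are bisected
up to 4 levels.  Iterates that invert an element or overflow the
exponential laws are rejected by a simple backtracking line search.

The element tangent is assembled by central finite differences of the
(energy-consistent) internal force, batched over all elements and all
24 DOF perturbations in single vectorized evaluations; spring tangents
are analytic.  The global system (≈ 850 DOFs for one muscle, ≈ 1700 for
the epimuscular pair) is factorized directly.  The tangent is
symmetrized; its agreement with the finite-difference Jacobian of the
residual is itself a test.

## Post-processing

Fiber-direction Green–Lagrange strains of the fiber mesh are
extrapolated from Gauss points to element nodes with the standard
trilinear (√3) extrapolation and averaged over adjacent elements, then
sampled on the (face, section, interface) grid; percentages in CSV
output are rounded to 0.1.  Because the sections are nodal planes and
the recovery scheme is not uniquely defined by the sampling description,
per-section extrema are mildly scheme-dependent; the averaged scheme was
chosen for robustness.  Myofascial loads are the projections of the
extra-/intermuscular link forces on the mean local fiber direction at
the attachment node, normalized by the single largest magnitude over the
three cases of a variant; a negative fiber-direction component (the
fiber axis is oriented distally) is reported as proximally directed.
The proximo-distal balance report checks that the difference between the
end reactions equals the summed axial myofascial load — an independent
global-equilibrium closure.

## What the tests do and do not show

The verification suite establishes internal mechanical consistency
(forces are energy gradients to 10⁻⁶, tangents match residual
differentiation to 10⁻⁵, equilibrium closes to 0.5% of the largest
reaction, solutions are step-size invariant and objective) and the
published qualitative mechanism: connected variants develop strain
regions opposing the imposed length change, with proximally directed
loads peaking in the passive-lengthening case.  Because the contour,
aponeurosis constants and link placement are approximations, the
absolute strain percentages of the connected variants should not be read
as predictions for the real muscle; only their signs, orderings and
responses to stiffness scaling are asserted.  Force–velocity behaviour,
viscoelasticity, history effects and submaximal rate coding are outside
the model by design.

## Problem sizes

All shipped analyses use the default mesh (96 muscle + 34 aponeurosis
elements per muscle, two muscles in the epimuscular variant).  A full
scenario solves in seconds to ~half a minute on one CPU; the complete
test suite including every variant × case combination runs in a few
minutes.
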