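# Methods

This note records the models implemented by `neuroplate`, the conventions
and parameter choices the code commits to where the underlying model
leaves them open, and the limits of what the test suite shows.

## Cell-division geometry (`cell_division`)

A dividing cell's cortex is a bundle of `n_meridians` rational Bézier
curves sharing one meridian control polygon, rotated about the polar
axis (z by default) through the division centre. Weights are complex;
with complex W the curve B(t) is complex-valued even for real control
points, so a projection rule fixes the geometric realisation. The
default takes the real part per coordinate; a signed-modulus projection
(|z| carrying the sign of Re z) is available by flag. The projection
choice does not affect the algebraic invariants (endpoint
interpolation, weight-scaling homogeneity), which are checked on the
complex curve itself.

The two-lobe post-division figure is produced by a `pinch` factor in
[0, 1] that pulls the equatorial control point toward the axis;
pinch = 0 degenerates to the pre-division convex lobe. The model stops
at the two-lobe stage deliberately: a tissue-scale tiling of division
bodies is out of scope, matching the observation that this approach
does not extend beyond single dividing cells.

Winding numbers are computed by summing signed angle increments along a
closed polyline; the sum must land within 1e−6 of an integer or the
curve is reported as undersampled rather than silently rounded. The
12-sphere cuboctahedral arrangement (`cuboctahedral_centers`) is a
plotting preset only — the kissing-number analogy is not an
optimisation problem here.

## Neural-tube model (`neural_tube`)

The triple {C, S, S′} is built as S = C + A·w(fx), S′ = C − A·w(fx), so
the mirror identity S + S′ − 2C = 0 holds by construction and is
re-verified to 1e−9. The oscillatory envelope w links the curve model
to the field L = ζ(e^{iπxy}): the "zeta" envelope is sin(arg L) on a
fixed y-slice (default y = 1), which oscillates and changes sign where
the field is real. A plain sine envelope is the reference case for
crossing-count tests. Crossings are sign changes of S − C refined by
bisection to 1e−8, with a half-open interval convention so a crossing
at a shared sample is reported once and the domain endpoints are not
crossings.

The unit-neuron field F = e^{πTxy} takes T = θ(t) as a per-field
constant: the "eq5" variant leaves t free (default 1), the "eq4"
variant derives it from the integer index n through the Lambert-W clock
t = 2π(n + 1/8)/W₀(e^{−n−1/8}). The default grid is the model's stated
domain x ∈ [−20, 20], y ∈ [0.1, 1] at 400×100; evaluation is a single
vectorised exponential after one theta evaluation, so the full domain
costs milliseconds.

### The two theta conventions

The theta formula attached to the field equations subtracts two
identical log-gamma terms as written, which collapses to −ln(πt)/2 and
cannot produce a structured field. The companion formulation used by
the growth chain shows the conjugate pair, and that is what `printed`
mode implements:

θ(t) = −ln(πt)/2 − (i/2)[lnΓ(1/4 + it/4) − lnΓ(1/4 − it/4)],

which is real for t > 0 because the bracket is purely imaginary.
`standard` mode is the textbook Riemann–Siegel theta
arg Γ(1/4 + it/2) − (t/2)ln π, odd in t and defined for all real t.
Both run through mpmath log-gamma at 30 decimal digits (continuous
branch, so θ is continuous in t) and are rounded to float on return.
`printed` is the default because it is the variant the growth chain
θ(Gₙ, t) generalises (g = 1 recovers it exactly).

The clock t = 2π(n+1/8)/W₀(e^{−n−1/8}) is implemented exactly as
specified, although it differs from the standard Gram-point
asymptotic; it is monotone in n, and n ∈ [−2, 6] gives t from −7.95 to
1.76e4 (negative t values are masked when they reach printed-mode
theta). Whether ζ here is the Riemann zeta is not stated in the source
model; the package implements Riemann zeta via analytic continuation on
the unit circle, masking a disc of radius 1e−6 around argument 1 (the
only pole). The phase parameter "xy" enters periodically (period 2), so
grid evaluation caches by residue.

## Plate growth (`plate_growth`)

**Numerical maps.** Layer k of the lattice holds as many nodes as row k
of the growth map has coefficients — 0-based rows, so the Pascal map
gives layer k exactly k+1 cells and ten growth steps from a single seed
cell produce Σ_{k=0..10}(k+1) = 66 nodes. Hermite rows (physicists'
convention, generated by symbolic differentiation of the Rodrigues
formula and cross-checked against the three-term recurrence) are the
built-in alternative map; `custom` rows are the extension point for
tissue-specific "magic numbers", which are deliberately not invented
here — discovering them is future work in the underlying model.

**Growth step.** `grow_layer` resamples the previous layer's curve at
the new row's knot count, lifts by `z_step` (default 1.0), and
displaces laterally by W ⊙ ΔM where ΔM is the increment of the property
vector M under one midpoint Runge–Kutta step. The equation of motion
for M is not fixed by the model; the default is linear relaxation
dM/dt = −κ(M − M_target) with κ = 1, M_target = 0, chosen as the
simplest stable dynamics, and any f(t, M) can be supplied. With frozen
dynamics (f ≡ 0) the step is exactly a z-lift of the resampled curve,
which makes it a per-layer isometry — both properties are tested to
1e−12. An exhausted map is a stop signal (`lattice.exhausted`), not an
error. Layer curves store the new nodes as control points with scalar
weights ‖W‖ per node; the "interpolates its nodes" reading is exact at
endpoints and for the collinear default geometry, where the Bézier of
equally spaced collinear control points is the segment itself.

**Runge–Kutta convention.** The printed scheme's K₁ = "hf(xₙ + yₙ)" is
read as K₁ = h·f(xₙ, yₙ) (comma, not sum): with the sum reading K₂'s
two-argument signature is inconsistent, and the scheme is then the
classical midpoint method with O(h³) local truncation. The observed
global order on y′ = −y is verified to lie in [1.9, 2.1].

**PDE chain.** The curl N = ∇×G is available symbolically (sympy) and
by central differences. The model's printed dependence
(G₁(X), G₂(Y), G₃(Z)) makes N ≡ 0 — this separable case is kept as the
documented degenerate default, and general G(X,Y,Z) components are
accepted so the mixed-derivative coefficients Bₙ of the PDE can be
nonzero. The PDE D = A E_GG + Bₙ E_Gθ + C E_θθ + D E_G + E E_θ
(A = C = D = E = 1 unless overridden) is discretised with second-order
central stencils, one-sided second-order stencils on boundary rows, and
the mixed term as composed first-derivative operators; the
mixed-derivative notation "∂Gₙθₙ" is read as ∂²/∂Gₙ∂θₙ. Against the
symbolic oracle on E = e^{Gθ} the scheme is accurate to < 1e−6 at
h = 1e−3 and shows the expected ≥ 3.5× error contraction per halving.

**D → W.** The mapping from PDE responses to curve weights is
under-specified in the model ("generates input D for W"); the package
uses W = (|D| + ε)/Σ(|D| + ε) with ε = 1e−9: positive, scale-free,
permutation-equivariant, and uniform (1/3 each) at zero response —
the minimal assumptions a rational-Bézier weight vector needs.

**Singularity removal.** Growth polynomials are generated from the
binomial formula, so t₅ = x⁵ + 5x⁴y + 10x³y² + 10x²y³ + 5xy⁴ + y⁵. (The
source model prints the fifth term as "5xy³", which breaks the binomial
pattern; this is treated as a typographical slip — the removed term and
every other coefficient match.) `remove_singularity(t₅, 3)` deletes
exactly 10x³y², logging it so `restore_term` can rebuild the original
exactly. Removal is guarded by a Laurent-replaceability hook: when a
local function around the flagged point is supplied and its
negative-order Laurent coefficients (trapezoid contour quadrature,
≥ 256 samples) are finite, the singularity is replaceable and the term
is kept; with no local function the point is not replaceable and
removal proceeds.

**Elliptic lattices.** Point enumeration is exhaustive via a
quadratic-residue table, capped at p ≤ 10⁴ so the scan stays well under
a second; larger p is rejected rather than switching algorithms. The
projective set is the point at infinity (0:1:0) plus the z = 1 slice,
which equals the affine set. No group law is implemented — the curve is
a placement lattice, not an arithmetic object. Placed neurons get
parametric stand-in bodies (ellipsoid / tapered-cone presets labelled
as such); the original study's exact pyramidal and non-pyramidal shape
equations are not reproduced here, only distinguished by construction
(different bounding-box aspect ratios). Points sharing an (x, y)
residue stack along z at `z_step` intervals.

## Control layer (`dynamics_logic`)

**Van der Pol.** Only ẋ₂ = −x₁ − m(x₁²−1)x₂ is given by the model;
ẋ₁ = x₂ is supplied as the standard phase-plane companion (a
one-equation field is not integrable). Presets m = 0.1 and m = 1; the
m = 0 harmonic limit conserves x₁²+x₂² to < 1e−3 per period at
h = 1e−3, and the m = 0.1 limit cycle has amplitude ≈ 2 (verified in
[1.9, 2.1] by long integration).

**Gibbs gating.** G = U + pV − TS and dG = −S dT + V dp + Σ μᵢ dnᵢ;
the sign convention for "can proceed" is not stated in the model, so
the standard thermodynamic convention is adopted: proceed iff dG < 0
(strict).

**Boolean differentials.** ⊕ is XOR; truth tables are little-endian
index-aligned with the bit vectors. d = f(X) ⊕ f(X⊕dX),
min = ∧, max = ∨; the identity d = max ⊕ min is checked exhaustively at
arity 2 (256 cases). The growth gate takes factor bits directly —
how the field values α(E) and β(C) are thresholded into bits is left to
configuration, since the model does not specify it — and admits exactly
the single-bit flips of the gate graph; the gated integral accumulates
the wedge-product integrand over steps with g = 1.

**Forms.** K-forms are constant-coefficient at the evaluation point,
stored on strictly increasing index tuples. The wedge permutation sum
runs over S(k+l) with the 1/(k!l!) normalisation (the truncated upper
index in the printed sum is read as k+l), giving graded commutativity
α∧β = (−1)^{kl} β∧α, which is tested against the direct k-form
determinant evaluation.

**Categories.** Everything is finite and checked exhaustively:
associativity and identity laws for categories, typing/identity/
composition preservation for functors (functor-law violations are
precondition errors, not naturality failures), and the commuting square
C(f)∘Φ(M1) = Φ(M2)∘E(f) for every morphism, returning the first
counterexample. Φ components are data — the model assigns them no
biological closed form — and fixtures generate valid and invalid ones.

**Topology.** The checker reports rather than assumes: ∅/X membership,
closure under unions and intersections, NC-family intersections both
pairwise and total (the printed condition is ambiguous between the
two, so both are reported), literal Hausdorff separation (with the
warning that finite Hausdorff forces discreteness), Lindelöf (trivially
true for finite spaces), and validity of a supplied identification map
(surjectivity + open preimages). No quotient construction is performed.

**Shape operator.** From the first and second fundamental forms,
S = I⁻¹II in the (r_u, r_v) basis; sympy patches are differentiated
exactly (closed-form curvatures for sphere/cylinder/plane verified to
1e−8), callable patches fall back to central differences at h = 1e−4
and are cross-checked against a −∇_v N normal-derivative oracle to
1e−5.

## Fixtures, seeds and I/O

Fixture generation hashes (kind, seed) into independent generator
streams, so adding a fixture kind never shifts another's draws, and
regeneration is byte-identical. Geometry output is ASCII only (OBJ
polylines, PLY point clouds, CSV, JSON reports) for bit-exact diffs;
config schemas are strict (unknown keys rejected by name) so every
model-gap decision above remains visible in configuration.

## Problem sizes

The test suite and the acceptance script use: plate growth to layer 10
(66 nodes), elliptic enumeration for all p ≤ 97 with a, b ∈ {0..4},
Boolean exhaustion at arity 2 with sampling at arity 3, Van der Pol
integrations of 2×10⁴ steps at h = 10⁻², PDE grids of 201² at
h = 10⁻³, and 400×100 unit-neuron fields. These sizes exercise every
code path at full fidelity — the algorithms are exact or
spectrally/quadratically convergent, so larger sizes change runtimes,
not conclusions.

## What passing tests do and do not show

The generators emulate the *mathematical* study conditions (parameter
ranges, map choices, printed coefficient tables), not biological data:
there is no noise model, no measured cell positions, and no claim that
the Pascal map is the true cortical "magic number" sequence (the
underlying model explicitly leaves that to future work). Passing tests
therefore certify the engine's algebra, numerics and logic — not
biological validity. Known limitations: the separable default makes the
PDE's mixed terms vanish (documented above); the division model stops
at two lobes; the unit neuron is not integrated into the triple-curve
CNS model (the model itself found that integration limited); and the
Hausdorff check on finite spaces is of diagnostic value only.
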