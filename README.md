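# neuroplate

A generative-geometry and growth-logic engine for mathematical models of
embryonic neurodevelopment. It implements, as tested library code, three
complementary views of early central-nervous-system formation together
with the logical/topological control layer that gates growth:

1. **Cell division** — the "cellular cortex" (the actin–myosin shell of a
   dividing cell) is modelled by bundles of rational Bézier curves with
   *complex* control weights,

   B(t) = Σᵢ b_{i,n}(t) Pᵢ Wᵢ / Σᵢ b_{i,n}(t) Wᵢ,  b_{i,n}(t) = C(n,i) tⁱ(1−t)^{n−i},

   arranged radially about the division centre, with a winding-number
   routine quantifying how a cortex curve encircles the centre.

2. **Neural tube** — the midline and two hemispheres as a mirrored triple
   of curves B = {C, S, S′} with S, S′ crossing C wherever an oscillatory
   envelope (derived from the phase of L = ζ(e^{iπxy})) changes sign, and
   a single-neuron unit field F = e^{πTxy} with T = θ(t), where θ is the
   Riemann–Siegel theta function and t comes from the Lambert-W clock
   t = 2π(n + 1/8) / W₀(e^{−n−1/8}).

3. **Neural plate** — layered tissue growth along z driven by a numerical
   map (Pascal's triangle by default: layer n holds n+1 cells; Hermite
   rows as the analogous map), binomial growth polynomials
   tₙ = (x+y)ⁿ with removable singular terms (t₅ → t₅,₂ deletes 10x³y²),
   property vectors M advanced by a midpoint Runge–Kutta step
   (M_{t+dt} = M_t + M_dt), curve weights W produced by a second-order
   PDE D = A E_GG + Bₙ E_Gθ + C E_θθ + D E_G + E E_θ on the exponential
   field E(Gₙ, θₙ) with Bₙ from ∇×G, and neuron placement on the rational
   points of an elliptic curve y² = x³ + ax + b over a finite field.

The **control layer** supplies a Van der Pol electrical field
(ẋ₂ = −x₁ − m(x₁²−1)x₂), Gibbs free-energy gating (G = U + pV − TS,
dG = −S dT + V dp + Σ μᵢ dnᵢ; growth proceeds iff dG < 0), Boolean
differential calculus (d_X f = f(X) ⊕ f(X⊕dX), with ∧/∨ min–max
variants and the single-bit-flip growth gate), wedge products of
differential k-forms, functor/natural-transformation commutation checks
(Cf ∘ Φ(M1) = Φ(M2) ∘ Ef), finite-topology axiom reports, and the shape
operator S_p(v) = −∇_v N with principal curvatures.

Intended users: researchers prototyping morphogenesis simulations and
developmental models who need the geometric and logical primitives above
with verified numerics, plus plain-text exports (OBJ/PLY/CSV/JSON) for
downstream visualisation.

## Worked example

```python
import numpy as np
from neuroplate.plate_growth import (
    GrowthMap, TissueLattice, grow, growth_polynomial, remove_singularity,
    elliptic_projective_points,
)
from neuroplate.math_core import gram_time, riemann_siegel_theta

# Pascal-map plate growth to layer 10
lat = grow(TissueLattice.seed(GrowthMap.pascal(11)), 10)
print(lat.node_count)                 # 66  (= 1+2+...+11 cells)

# binomial growth polynomial with the singular term removed
t5 = growth_polynomial(5)
t52 = remove_singularity(t5, 3)
print(t5.coefficients())              # (1, 5, 10, 10, 5, 1)
print(t52.coefficients())             # (1, 5, 10, 5, 1)
print(t5.evaluate(1, 1) - t52.evaluate(1, 1))   # 10.0 — the removed 10 x^3 y^2

# Lambert-W clock and the theta phase driving the unit-neuron field
print(round(gram_time(0), 6))         # 1.501546
print(round(riemann_siegel_theta(1.0), 6))      # -1.411235

# elliptic placement lattice over F_5 (y^2 = x^3 + x)
lat5 = elliptic_projective_points(1, 0, 5)
print(len(lat5.affine_points), len(lat5.projective_points))   # 3 4
```

The printed numbers mean: the Pascal map dictates 66 cells after ten
growth steps; deleting the third monomial of t₅ removes exactly the
coefficient-10 term; the Gram-time clock at n = 0 gives t ≈ 1.5015 whose
theta phase θ ≈ −1.4112 scales the unit-neuron field; and the F₅ curve
carries 3 affine points plus the point at infinity for neuron placement.

A command-line interface mirrors the library:

```bash
neuroplate grow --map pascal --layers 10 --out plate.ply
neuroplate lattice --a 1 --b 0 --p 5 --projective --out pts.csv
neuroplate divide --n-meridians 12 --stage post_division --pinch 0.8 --seed 7 --out body.obj
```

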