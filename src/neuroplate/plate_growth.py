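"""Neural-plate growth: numerical-map layer growth with PDE-weighted curves.

The plate grows layer by layer along z according to a numerical map — by
default Pascal's triangle, whose row n fixes how many cells layer n
holds ("magic numbers" in the tissue's own map).  Binomial growth
polynomials t_n = (x+y)^n describe each layer's curvilinear section; a
singular cell type corresponds to a removable monomial (t5 -> t5,2).

Cellular property vectors M evolve by a midpoint Runge-Kutta step and
displace the new layer's nodes; the control weights W of each layer's
rational Bezier curve come from a second-order PDE applied to the
exponential field E(G_n, theta_n), with the mixed-term coefficients B_n
supplied by the curl of the cellular property field G.

Neuron placement uses the rational points of an elliptic curve over a
finite field as the deterministic lattice of nucleolus positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import mpmath
import numpy as np
import sympy

from .cell_division import ControlPolygon, rational_bezier
from .math_core import CoefficientRow, RowKind, laurent_coefficients, pascal_row, rk2_step

_PRIME_CAP = 10_000  # exhaustive enumeration stays < 1 s below this
_EXP_CAP = 700.0  # exponent clamp for E components (float64 overflow guard)


# ---------------------------------------------------------------------------
# growth polynomials


@dataclass(frozen=True)
class Monomial:
    coefficient: int
    x_power: int
    y_power: int

    def evaluate(self, x: float, y: float) -> float:
        return self.coefficient * x**self.x_power * y**self.y_power


@dataclass
class GrowthPolynomial:
    """Binomial growth polynomial t_n = (x+y)^n with removable singular terms."""

    degree: int
    monomials: list  # list[Monomial], descending x-power
    removed_terms: list = field(default_factory=list)  # [(ordinal, Monomial)]

    def evaluate(self, x: float, y: float) -> float:
        return sum(m.evaluate(x, y) for m in self.monomials)

    def coefficients(self) -> tuple:
        return tuple(m.coefficient for m in self.monomials)


def growth_polynomial(n: int) -> GrowthPolynomial:
    """The degree-n binomial expansion B = Σ_k C(n,k) x^{n−k} y^k."""
    if n < 1:
        raise ValueError("degree must be >= 1")
    row = pascal_row(n)
    monos = [
        Monomial(c, n - k, k) for k, c in enumerate(row.coefficients)
    ]
    return GrowthPolynomial(n, monos)


def is_laurent_replaceable(
    local_function: Callable[[complex], complex] | None,
    center: complex = 0.0,
    radius: float = 0.5,
    negative_orders: Sequence[int] = (-1, -2, -3),
) -> bool:
    """Whether a singular point is replaceable by a Laurent expansion.

    A singularity is replaceable when the supplied local function admits
    finite Laurent coefficients at the requested negative orders on a
    small contour around the flagged point (an isolated singularity).
    With no local function supplied the point is treated as not
    replaceable, so removal proceeds.
    """
    if local_function is None:
        return False
    try:
        coeffs = laurent_coefficients(local_function, center, negative_orders, radius)
    except (ArithmeticError, ZeroDivisionError, ValueError, OverflowError):
        return False
    return all(np.isfinite(c.real) and np.isfinite(c.imag) for c in coeffs)


def remove_singularity(
    poly: GrowthPolynomial,
    ordinal: int,
    local_function: Callable[[complex], complex] | None = None,
    **laurent_kwargs,
) -> GrowthPolynomial:
    """Remove the ``ordinal``-th monomial (1-based) as a singular cell type.

    Removal only proceeds when the singular point is *not* replaceable by
    a Laurent expansion of the supplied local function; a replaceable
    singularity leaves the polynomial unchanged.  The removed monomial is
    logged in ``removed_terms`` so it can be restored exactly.
    """
    if not (1 <= ordinal <= len(poly.monomials)):
        raise IndexError(
            f"ordinal {ordinal} outside 1..{len(poly.monomials)}"
        )
    if is_laurent_replaceable(local_function, **laurent_kwargs):
        return GrowthPolynomial(
            poly.degree, list(poly.monomials), list(poly.removed_terms)
        )
    monos = list(poly.monomials)
    removed = monos.pop(ordinal - 1)
    return GrowthPolynomial(
        poly.degree, monos, list(poly.removed_terms) + [(ordinal, removed)]
    )


def restore_term(poly: GrowthPolynomial, ordinal: int) -> GrowthPolynomial:
    """Re-insert a previously removed monomial at its original ordinal."""
    for i, (orig_ordinal, mono) in enumerate(poly.removed_terms):
        if orig_ordinal == ordinal:
            monos = list(poly.monomials)
            monos.insert(orig_ordinal - 1, mono)
            removed = list(poly.removed_terms)
            removed.pop(i)
            return GrowthPolynomial(poly.degree, monos, removed)
    raise KeyError(f"no removed term logged at ordinal {ordinal}")


# ---------------------------------------------------------------------------
# growth maps and lattices


@dataclass
class GrowthMap:
    """Numerical map: one coefficient row per layer, plus the z step."""

    kind: RowKind
    rows: list  # list[CoefficientRow]
    z_step: float = 1.0

    def __post_init__(self) -> None:
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        for r in self.rows:
            if len(r.coefficients) == 0:
                raise ValueError("rows must be non-empty")

    @classmethod
    def pascal(cls, n_rows: int, z_step: float = 1.0) -> "GrowthMap":
        return cls(RowKind.PASCAL, [pascal_row(k) for k in range(n_rows)], z_step)


class ShapeClass(str, Enum):
    SPHERE = "sphere"
    ELLIPSOID = "ellipsoid"
    PYRAMIDAL_APPROX = "pyramidal_approx"
    CONVEX = "convex"


class ElectricalClass(str, Enum):
    EXCITATORY = "+"
    INHIBITORY = "-"
    MIXED = "+-"


@dataclass
class CellNode:
    position: np.ndarray  # 3D
    shape_class: ShapeClass = ShapeClass.SPHERE
    electrical_class: ElectricalClass = ElectricalClass.EXCITATORY
    M: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.M.size < 3:
            raise ValueError("property vector M must have length >= 3")
        if not np.all(np.isfinite(self.M)):
            raise ValueError("property vector M must be finite")

    @property
    def nucleolus(self) -> np.ndarray:
        return self.position


@dataclass
class TissueLattice:
    """The growing plate: ordered layers of cells with per-layer curves."""

    layers: list = field(default_factory=list)  # list[list[CellNode]]
    layer_curves: list = field(default_factory=list)  # list[ControlPolygon]
    growth_map: GrowthMap | None = None
    t: float = 0.0
    exhausted: bool = False

    @classmethod
    def seed(
        cls,
        growth_map: GrowthMap,
        origin=(0.0, 0.0, 0.0),
        M0=(0.0, 0.0, 0.0),
    ) -> "TissueLattice":
        """Layer 0: the nodes demanded by the map's first row, at the origin."""
        row = growth_map.rows[0]
        count = len(row.coefficients)
        origin = np.asarray(origin, dtype=float)
        nodes = [
            CellNode(origin + np.array([j * 1.0, 0.0, 0.0]), M=np.array(M0, float))
            for j in range(count)
        ]
        lat = cls(growth_map=growth_map)
        lat.layers.append(nodes)
        lat.layer_curves.append(_curve_through(nodes, np.ones(count)))
        return lat

    @property
    def node_count(self) -> int:
        return sum(len(layer) for layer in self.layers)


def _curve_through(nodes: list, weights: np.ndarray) -> ControlPolygon:
    pts = np.array([n.position for n in nodes], dtype=float)
    if pts.shape[0] == 1:  # degenerate single-node layer: a point "curve"
        pts = np.vstack([pts, pts])
        weights = np.array([weights[0], weights[0]])
    return ControlPolygon(pts, np.asarray(weights, dtype=complex))


def _resample_curve(curve: ControlPolygon, count: int) -> np.ndarray:
    knots = np.linspace(0.0, 1.0, count) if count > 1 else np.array([0.5])
    _, pts = rational_bezier(curve, knots)
    return np.atleast_2d(pts)


def grow_layer(
    lattice: TissueLattice,
    growth_map: GrowthMap | None = None,
    dt: float = 0.1,
    dynamics: Callable | None = None,
    weights: np.ndarray | None = None,
) -> TissueLattice:
    """Append the next layer of the plate: M_{t+dt} = M_t + M_dt.

    The new layer k holds as many nodes as the map's row k has
    coefficients.  Node positions are the previous layer's curve
    resampled at the new knots, lifted by z_step and laterally displaced
    by the W-weighted increment of the property vector M, which advances
    by one midpoint Runge-Kutta step of ``dynamics`` (dM/dt = f(t, M);
    default linear relaxation dM/dt = −κ(M − M_target) with κ = 1,
    M_target = 0).  ``weights`` is an (count, 3) array of per-node W
    weights (positive, each row summing to 1); default uniform.

    When the map has no further rows the lattice is returned unchanged
    with ``exhausted`` set — a stop signal, not an error.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    gmap = growth_map or lattice.growth_map
    if gmap is None:
        raise ValueError("no growth map available")
    k = len(lattice.layers)
    if k >= len(gmap.rows):
        lattice.exhausted = True
        return lattice
    if dynamics is None:
        dynamics = lambda t, M: -(M - 0.0)  # noqa: E731  kappa=1, target=0
    count = len(gmap.rows[k].coefficients)
    prev_nodes = lattice.layers[-1]
    prev_curve = lattice.layer_curves[-1]
    base = _resample_curve(prev_curve, count)

    if weights is None:
        W = np.full((count, 3), 1.0 / 3.0)
    else:
        W = np.asarray(weights, dtype=float)
        if W.shape != (count, 3):
            raise ValueError(f"weights must have shape ({count}, 3)")

    # interpolate the previous layer's M onto the new knots
    prev_M = np.array([n.M for n in prev_nodes], dtype=float)
    old_u = np.linspace(0.0, 1.0, len(prev_nodes)) if len(prev_nodes) > 1 else [0.0]
    new_u = np.linspace(0.0, 1.0, count) if count > 1 else [0.5]
    M_interp = np.stack(
        [np.interp(new_u, old_u, prev_M[:, c]) for c in range(prev_M.shape[1])],
        axis=1,
    )

    new_nodes = []
    for j in range(count):
        M_new = rk2_step(dynamics, lattice.t, M_interp[j], dt)
        dM = np.asarray(M_new) - M_interp[j]
        pos = base[j] + np.array([0.0, 0.0, gmap.z_step]) + W[j] * dM[:3]
        new_nodes.append(CellNode(pos, M=np.asarray(M_new)))
    lattice.layers.append(new_nodes)
    lattice.layer_curves.append(_curve_through(new_nodes, np.linalg.norm(W, axis=1)))
    lattice.t += dt
    return lattice


def grow(
    lattice: TissueLattice,
    n_layers: int,
    dt: float = 0.1,
    dynamics: Callable | None = None,
) -> TissueLattice:
    """Grow up to ``n_layers`` additional layers (stops when the map runs out)."""
    for _ in range(n_layers):
        grow_layer(lattice, dt=dt, dynamics=dynamics)
        if lattice.exhausted:
            break
    return lattice


def layer_bijection(layer_a: list, layer_b: list) -> dict:
    """Index-aligned map between two layers, Cayley-table style.

    Bijective exactly when the layers have equal node counts; otherwise
    the unmatched trailing nodes of the larger layer are listed.
    """
    na, nb = len(layer_a), len(layer_b)
    m = min(na, nb)
    return {
        "mapping": list(zip(range(m), range(m))),
        "is_bijective": na == nb,
        "unmatched": list(range(m, max(na, nb))),
        "unmatched_side": "a" if na > nb else ("b" if nb > na else None),
    }


def compose_bijections(map_ab: dict, map_bc: dict) -> dict:
    """Compose two layer maps; the composite of bijections is bijective."""
    ab = dict(map_ab["mapping"])
    bc = dict(map_bc["mapping"])
    comp = [(i, bc[j]) for i, j in ab.items() if j in bc]
    return {
        "mapping": comp,
        "is_bijective": map_ab["is_bijective"] and map_bc["is_bijective"],
        "unmatched": [],
        "unmatched_side": None,
    }


# ---------------------------------------------------------------------------
# curl / theta / exponential / PDE chain


def curl(G, mode: str = "symbolic", h: float = 1e-3, at=None):
    """Curl N = ∇ × G of a 3-component field over (X, Y, Z).

    mode="symbolic": G is a triple of sympy expressions in symbols X, Y, Z;
    returns sympy expressions for the three components.
    mode="fd": G is a triple of callables G_k(X, Y, Z); returns the three
    components evaluated at the point ``at`` by central differences with
    spacing ``h``.

    For the separable dependence (G₁(X), G₂(Y), G₃(Z)) every
    cross-derivative vanishes and N ≡ 0 — the documented degenerate
    default of the model; general G(X, Y, Z) components give nonzero N.
    """
    if mode == "symbolic":
        X, Y, Z = sympy.symbols("X Y Z")
        gx, gy, gz = (sympy.sympify(g) for g in G)
        return (
            sympy.simplify(sympy.diff(gz, Y) - sympy.diff(gy, Z)),
            sympy.simplify(sympy.diff(gx, Z) - sympy.diff(gz, X)),
            sympy.simplify(sympy.diff(gy, X) - sympy.diff(gx, Y)),
        )
    if mode != "fd":
        raise ValueError("mode must be 'symbolic' or 'fd'")
    if at is None:
        raise ValueError("fd mode requires the evaluation point 'at'")
    gx, gy, gz = G
    p = np.asarray(at, dtype=float)

    def d(f, axis):
        e = np.zeros(3)
        e[axis] = h
        return (f(*(p + e)) - f(*(p - e))) / (2.0 * h)

    n = (
        d(gz, 1) - d(gy, 2),
        d(gx, 2) - d(gz, 0),
        d(gy, 0) - d(gx, 1),
    )
    if not all(np.isfinite(v) for v in n):
        raise ArithmeticError(f"non-finite curl derivative at {at}")
    return n


def theta_of_G(g: float, t: float) -> float:
    """θ(G_n, t) = −ln(πt)/2 − (i/2)[lnΓ(1/4 + tg·i/4) − lnΓ(1/4 − tg·i/4)].

    The conjugate gamma pair makes the bracket purely imaginary, so the
    value is real for real g, t; g = 0 collapses to −ln(πt)/2, and g = 1
    recovers the printed-mode Riemann–Siegel theta.
    """
    if t <= 0:
        raise ValueError("theta_of_G requires t > 0")
    with mpmath.workdps(30):
        bracket = mpmath.loggamma(mpmath.mpf("0.25") + 0.25j * t * g) - mpmath.loggamma(
            mpmath.mpf("0.25") - 0.25j * t * g
        )
        val = -mpmath.log(mpmath.pi * t) / 2 - 0.5j * bracket
    return float(mpmath.re(val))


def E_components(G, theta) -> np.ndarray:
    """E(G_n, θ_n) = (e^{G_X π θ₁}, e^{G_Y π θ₂}, e^{G_Z π θ₃}); positive.

    Exponents beyond the float64 range are clamped at ±700 with a warning.
    """
    import warnings

    G = np.asarray(G, dtype=float)
    theta = np.asarray(theta, dtype=float)
    expo = G * math.pi * theta
    if np.any(np.abs(expo) > _EXP_CAP):
        warnings.warn("E_components exponent clamped to avoid overflow")
        expo = np.clip(expo, -_EXP_CAP, _EXP_CAP)
    return np.exp(expo)


@dataclass
class PDEOperator:
    """Coefficients of the second-order growth PDE (A = C = D = E = 1)."""

    A: float = 1.0
    C: float = 1.0
    D: float = 1.0
    E: float = 1.0
    B: tuple = (0.0, 0.0, 0.0)  # mixed-term coefficients from the curl
    h: float = 1e-3


def _d1(F: np.ndarray, h: float, axis: int) -> np.ndarray:
    """First derivative, 2nd-order central interior / one-sided boundaries."""
    return np.gradient(F, h, axis=axis, edge_order=2)


def _d2(F: np.ndarray, h: float, axis: int) -> np.ndarray:
    """Second derivative, 2nd-order central interior / one-sided boundaries."""
    F = np.moveaxis(F, axis, 0)
    out = np.empty_like(F)
    out[1:-1] = (F[2:] - 2.0 * F[1:-1] + F[:-2]) / h**2
    out[0] = (2.0 * F[0] - 5.0 * F[1] + 4.0 * F[2] - F[3]) / h**2
    out[-1] = (2.0 * F[-1] - 5.0 * F[-2] + 4.0 * F[-3] - F[-4]) / h**2
    return np.moveaxis(out, 0, axis)


def pde_D(op: PDEOperator, E_field: np.ndarray, component: int = 0) -> np.ndarray:
    """D_ê_n = A E_GG + B_n E_Gθ + C E_θθ + D E_G + E E_θ on a (G, θ) grid.

    ``E_field[i, j]`` samples E over G values (axis 0) and θ values
    (axis 1) with uniform spacing ``op.h``.  Second-order central
    stencils in the interior and one-sided second-order stencils on the
    boundary rows.
    """
    E_field = np.asarray(E_field, dtype=float)
    if E_field.ndim != 2 or min(E_field.shape) < 5:
        raise ValueError("E field grid must be at least 5x5")
    h = op.h
    if h <= 0:
        raise ValueError("grid spacing h must be positive")
    Bn = op.B[component]
    E_g = _d1(E_field, h, 0)
    E_th = _d1(E_field, h, 1)
    E_gg = _d2(E_field, h, 0)
    E_thth = _d2(E_field, h, 1)
    E_gth = _d1(E_g, h, 1)
    return op.A * E_gg + Bn * E_gth + op.C * E_thth + op.D * E_g + op.E * E_th


def weights_from_D(D, eps: float = 1e-9) -> np.ndarray:
    """Positive Bezier control weights W from the PDE responses D.

    W = (|D| + ε) normalised to sum 1 per node; zero response gives the
    uniform weight (1/3, 1/3, 1/3).  Scale-free and permutation
    equivariant.
    """
    D = np.asarray(D, dtype=float)
    mag = np.abs(D) + eps
    return mag / mag.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# elliptic-curve lattices over finite fields


def _check_prime(p: int) -> None:
    if p < 3 or p > _PRIME_CAP:
        raise ValueError(f"p must be an odd prime in [3, {_PRIME_CAP}]")
    if p % 2 == 0 or any(p % q == 0 for q in range(3, int(math.isqrt(p)) + 1, 2)):
        raise ValueError(f"p = {p} is not prime")


@dataclass
class EllipticLattice:
    """Rational points of y² = x³ + ax + b over F_p, used as a placement map."""

    p: int
    a: int
    b: int
    affine_points: list = field(default_factory=list)  # [(x, y)]
    projective_points: list = field(default_factory=list)  # [(x, y, z)]


def elliptic_affine_points(a: int, b: int, p: int) -> EllipticLattice:
    """All (x, y) ∈ F_p² with y² ≡ x³ + ax + b (mod p), lexicographic order.

    Exhaustive enumeration via a quadratic-residue table; p is capped at
    10⁴ to keep the scan well under a second.
    """
    _check_prime(p)
    a, b = a % p, b % p
    # square roots table: value -> sorted list of y with y^2 = value
    roots: dict[int, list[int]] = {}
    for y in range(p):
        roots.setdefault(y * y % p, []).append(y)
    pts = []
    for x in range(p):
        rhs = (x * x * x + a * x + b) % p
        for y in roots.get(rhs, []):
            pts.append((x, y))
    return EllipticLattice(p, a, b, affine_points=pts)


def elliptic_projective_points(a: int, b: int = 0, p: int = 5) -> EllipticLattice:
    """Projective classes of zy² ≡ x³ + axz² + bz³ over F_p.

    Normalised representatives: the point at infinity (0 : 1 : 0) plus
    the z = 1 slice, which equals the affine point set.
    """
    lat = elliptic_affine_points(a, b, p)
    proj = [(0, 1, 0)] + [(x, y, 1) for (x, y) in lat.affine_points]
    lat.projective_points = proj
    return lat


# ---------------------------------------------------------------------------
# neuron placement

#: Parametric stand-in bodies for the cell-shape classes (half-axes in
#: arbitrary units).  The pyramidal body is a tapered cone approximation
#: elongated along z; the non-pyramidal default is a unit sphere.
SHAPE_PRESETS = {
    ShapeClass.SPHERE: {"half_axes": (0.5, 0.5, 0.5), "taper": 0.0},
    ShapeClass.ELLIPSOID: {"half_axes": (0.6, 0.4, 0.3), "taper": 0.0},
    ShapeClass.PYRAMIDAL_APPROX: {"half_axes": (0.4, 0.4, 0.9), "taper": 0.7},
    ShapeClass.CONVEX: {"half_axes": (0.5, 0.5, 0.4), "taper": 0.2},
}


def shape_aspect_ratio(shape: ShapeClass) -> float:
    """Bounding-box aspect ratio (height / max lateral extent) of a preset."""
    ax = SHAPE_PRESETS[shape]["half_axes"]
    return ax[2] / max(ax[0], ax[1])


def place_neurons(
    points: Sequence,
    shape_class: ShapeClass | str = ShapeClass.SPHERE,
    electrical_class: ElectricalClass | str = ElectricalClass.EXCITATORY,
    z_step: float = 1.0,
) -> list:
    """One CellNode per lattice point, nucleolus at the point.

    2D points are lifted to z = 0; points sharing the same (x, y) stack
    vertically at multiples of ``z_step``, mirroring the columnar
    organisation of the projective lattice.
    """
    if len(points) == 0:
        raise ValueError("point list must be non-empty")
    shape = ShapeClass(shape_class)
    elec = ElectricalClass(electrical_class)
    seen: dict[tuple, int] = {}
    nodes = []
    for pt in points:
        pt = tuple(float(v) for v in pt)
        if len(pt) == 2:
            pt = (pt[0], pt[1], 0.0)
        elif len(pt) != 3:
            raise ValueError("points must be 2D or 3D")
        key = (pt[0], pt[1])
        lift = seen.get(key, 0)
        seen[key] = lift + 1
        pos = (pt[0], pt[1], pt[2] + lift * z_step)
        nodes.append(
            CellNode(np.array(pos), shape_class=shape, electrical_class=elec)
        )
    return nodes
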