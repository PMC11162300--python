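"""Control layer: electrical, chemical, logical and topological gating.

Cell growth is gated by three interacting factors: electrical activity
(a Van der Pol phase field E), chemical drive (Gibbs free energy, whose
differential's sign decides whether a reaction direction can proceed),
and the local state of the neuronal-cell manifold.  Their interaction
is expressed through differential forms (wedge products of the two
vector fields), Boolean differential calculus over the three factor
bits, and a category-theoretic naturality check that the electrical and
chemical functors commute through the natural transformation Φ.
Finite-topology axioms (Lindelöf, Hausdorff, quotient maps) are checked
exhaustively on the finite cell complexes used here, and the shape
operator supplies principal curvatures for cell-surface change.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy


# ---------------------------------------------------------------------------
# Van der Pol electrical field


@dataclass(frozen=True)
class VanDerPolParams:
    """Damping parameter m >= 0; presets m = 0.1 and m = 1."""

    m: float = 1.0

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("damping m must be >= 0")


def van_der_pol_field(x1: float, x2: float, params: VanDerPolParams):
    """Phase-plane vector field (ẋ₁, ẋ₂) of the Van der Pol oscillator.

    ẋ₂ = −x₁ − m(x₁² − 1)x₂ as printed; ẋ₁ = x₂ is the standard
    phase-plane companion equation.  m = 0 reduces to the harmonic
    oscillator; m > 0 produces the limit cycle of amplitude ≈ 2.
    """
    dx1 = x2
    dx2 = -x1 - params.m * (x1**2 - 1.0) * x2
    return dx1, dx2


def integrate_van_der_pol(
    x0, params: VanDerPolParams, h: float = 1e-3, steps: int = 100_000
) -> np.ndarray:
    """RK midpoint trajectory of the oscillator; rows are (x1, x2)."""
    from .math_core import rk2_step

    def rhs(t, y):
        return np.array(van_der_pol_field(y[0], y[1], params))

    traj = np.empty((steps + 1, 2))
    traj[0] = x0
    y = np.asarray(x0, dtype=float)
    for i in range(steps):
        y = rk2_step(rhs, i * h, y, h)
        traj[i + 1] = y
    return traj


# ---------------------------------------------------------------------------
# Gibbs free energy


@dataclass
class GibbsState:
    """Thermodynamic state: G = U + pV − TS with chemical species (μᵢ, nᵢ)."""

    U: float
    p: float
    V: float
    T: float
    S: float
    species: list = field(default_factory=list)  # [(mu_i, n_i)]

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("temperature must be >= 0")
        if self.V <= 0:
            raise ValueError("volume must be positive")


def gibbs_energy(state: GibbsState) -> float:
    """G = U + pV − TS."""
    return state.U + state.p * state.V - state.T * state.S


def gibbs_differential(
    state: GibbsState, dT: float, dp: float, dn: Sequence[float]
) -> tuple[float, bool]:
    """dG = −S dT + V dp + Σ μᵢ dnᵢ, and whether the process may proceed.

    ``proceed`` is True exactly when dG < 0 (strict): the spontaneous
    direction of the chemical drive that gates cell growth.
    """
    if len(dn) != len(state.species):
        raise ValueError(
            f"dn has {len(dn)} entries for {len(state.species)} species"
        )
    dG = -state.S * dT + state.V * dp + sum(
        mu * d for (mu, _n), d in zip(state.species, dn)
    )
    return dG, dG < 0


# ---------------------------------------------------------------------------
# Boolean differential calculus


@dataclass
class BooleanState:
    """Input bits X, perturbation bits dX, and a truth-table function f."""

    X: tuple
    dX: tuple
    table: tuple  # truth table of f over 2^arity entries, index = little-endian X

    def __post_init__(self) -> None:
        arity = len(self.X)
        if len(self.dX) != arity:
            raise ValueError("X and dX must have equal length")
        if arity > 16:
            raise ValueError("arity capped at 16")
        if len(self.table) != 2**arity:
            raise ValueError(f"truth table needs {2 ** arity} entries")
        for bits in (self.X, self.dX, self.table):
            if any(b not in (0, 1) for b in bits):
                raise ValueError("bits must be 0/1")

    def f(self, bits: Sequence[int]) -> int:
        idx = sum(b << i for i, b in enumerate(bits))
        return self.table[idx]


def _xor_bits(a: Sequence[int], b: Sequence[int]) -> tuple:
    return tuple(x ^ y for x, y in zip(a, b))


def boolean_total_differential(state: BooleanState) -> int:
    """d_X f = f(X) ⊕ f(X ⊕ dX): does the perturbation flip the output?"""
    return state.f(state.X) ^ state.f(_xor_bits(state.X, state.dX))


def boolean_min(state: BooleanState) -> int:
    """Total differential minimum: f(X) ∧ f(X ⊕ dX)."""
    return state.f(state.X) & state.f(_xor_bits(state.X, state.dX))


def boolean_max(state: BooleanState) -> int:
    """Total differential maximum: f(X) ∨ f(X ⊕ dX)."""
    return state.f(state.X) | state.f(_xor_bits(state.X, state.dX))


# ---------------------------------------------------------------------------
# growth gate


def growth_gate(
    state: tuple,
    next_state: tuple,
    transitions: Sequence[tuple],
) -> tuple[int, dict]:
    """Gate bit g for a requested factor-state change, with an event log.

    ``state`` and ``next_state`` are the factor bits (X1, X2, X3) from
    the electrical field α(E), the chemical field β(C) and the manifold
    differential d(NC); ``transitions`` lists the admissible
    (state, next_state) edges of the gate graph.  g = 1 exactly when the
    requested change lies on an admissible edge; a no-change request or
    an undefined transition gives g = 0 with the reason logged.
    """
    state = tuple(int(b) for b in state)
    next_state = tuple(int(b) for b in next_state)
    log = {"state": state, "next_state": next_state}
    if state == next_state:
        log["reason"] = "no change"
        return 0, log
    edge = (state, next_state)
    if edge in {(tuple(a), tuple(b)) for a, b in transitions}:
        log["reason"] = "admissible edge"
        return 1, log
    log["reason"] = "transition not in gate graph"
    return 0, log


def gated_integral(
    steps: Sequence[tuple],
    transitions: Sequence[tuple],
    integrand: Sequence[float],
    dt: float,
) -> tuple[float, list]:
    """Accumulate ∮ (α ∧ β)(…) dt over the steps that receive g = 1.

    ``steps`` is a sequence of (state, next_state) pairs; ``integrand``
    supplies the wedge-product value for each step.  Returns the
    integral and the per-step event log.
    """
    if len(steps) != len(integrand):
        raise ValueError("one integrand value per step required")
    total = 0.0
    logs = []
    for (s, ns), val in zip(steps, integrand):
        g, log = growth_gate(s, ns, transitions)
        if g:
            total += val * dt
        log["g"] = g
        logs.append(log)
    return total, logs


#: Admissible single-bit flips out of [0,0,0] and onward, as in the gate
#: graph: every edge flips exactly one factor bit.
def single_flip_transitions(arity: int = 3) -> list:
    """All (state, next) pairs differing in exactly one bit — the gate graph."""
    edges = []
    for bits in itertools.product((0, 1), repeat=arity):
        for i in range(arity):
            flipped = list(bits)
            flipped[i] ^= 1
            edges.append((bits, tuple(flipped)))
    return edges


# ---------------------------------------------------------------------------
# differential forms


@dataclass
class KForm:
    """Constant-coefficient differential k-form at a point.

    ``coefficients`` maps strictly increasing index tuples (i1 < … < ik)
    to real coefficients α_{i1…ik}; the form acts on k tangent vectors
    as Σ α_{i1…ik} det(rows i1…ik of the vector matrix).
    """

    degree: int
    dimension: int
    coefficients: Mapping

    def __post_init__(self) -> None:
        if self.degree > self.dimension:
            raise ValueError("degree must not exceed ambient dimension")
        for idx in self.coefficients:
            if len(idx) != self.degree:
                raise ValueError(f"index tuple {idx} has wrong length")
            if any(not 0 <= i < self.dimension for i in idx):
                raise ValueError(f"index tuple {idx} out of range")
            if list(idx) != sorted(set(idx)):
                raise ValueError(f"index tuple {idx} must be strictly increasing")


def kform_eval(form: KForm, vectors: Sequence) -> float:
    """Evaluate a k-form on k tangent vectors.

    Σ_{i1<…<ik} α_{i1…ik} · det of the selected components of the
    vectors; a 0-form is its scalar coefficient.
    """
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    if len(vectors) != form.degree:
        raise ValueError(
            f"{form.degree}-form needs {form.degree} vectors, got {len(vectors)}"
        )
    if form.degree == 0:
        return float(form.coefficients.get((), 0.0))
    V = np.stack(vectors, axis=1)  # (dim, k): column j is vector j
    total = 0.0
    for idx, coeff in form.coefficients.items():
        total += coeff * np.linalg.det(V[list(idx), :])
    return float(total)


def wedge_eval(alpha: KForm, beta: KForm, vectors: Sequence) -> float:
    """(α ∧ β)(v₁…v_{k+l}) by the antisymmetrised permutation sum.

    (1/(k! l!)) Σ_{σ ∈ S(k+l)} sign(σ) α(v_{σ(1)}…v_{σ(k)})
    β(v_{σ(k+1)}…v_{σ(k+l)}); satisfies α ∧ β = (−1)^{kl} β ∧ α.
    """
    k, l = alpha.degree, beta.degree
    if len(vectors) != k + l:
        raise ValueError(f"wedge of degrees {k}+{l} needs {k + l} vectors")
    if alpha.dimension != beta.dimension:
        raise ValueError("forms must share the ambient dimension")
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    total = 0.0
    for perm in itertools.permutations(range(k + l)):
        sign = _perm_sign(perm)
        a = kform_eval(alpha, [vectors[i] for i in perm[:k]])
        b = kform_eval(beta, [vectors[i] for i in perm[k:]])
        total += sign * a * b
    return total / (math.factorial(k) * math.factorial(l))


def _perm_sign(perm: Sequence[int]) -> int:
    sign = 1
    seen = [False] * len(perm)
    for i in range(len(perm)):
        if seen[i]:
            continue
        j, cycle = i, 0
        while not seen[j]:
            seen[j] = True
            j = perm[j]
            cycle += 1
        if cycle % 2 == 0:
            sign = -sign
    return sign


# ---------------------------------------------------------------------------
# finite categories, functors, natural transformations


@dataclass
class FiniteCategory:
    """Finite category: objects, typed morphisms, composition table, identities.

    ``morphisms`` maps name -> (source, target); ``composition`` maps
    (g, f) -> g∘f for every composable pair; ``identity`` maps each
    object to its identity morphism.  ``validate`` checks totality,
    associativity and the identity laws exhaustively.
    """

    objects: frozenset
    morphisms: dict  # name -> (src, dst)
    composition: dict  # (g_name, f_name) -> name, defined when dst(f)=src(g)
    identity: dict  # object -> morphism name

    def source(self, f: str) -> str:
        return self.morphisms[f][0]

    def target(self, f: str) -> str:
        return self.morphisms[f][1]

    def compose(self, g: str, f: str) -> str:
        """g ∘ f (apply f first)."""
        if self.target(f) != self.source(g):
            raise ValueError(f"morphisms {g} o {f} are not composable")
        return self.composition[(g, f)]

    def validate(self) -> None:
        for obj in self.objects:
            i = self.identity.get(obj)
            if i is None or self.morphisms[i] != (obj, obj):
                raise ValueError(f"missing or mistyped identity on {obj}")
        for f, (fs, ft) in self.morphisms.items():
            if fs not in self.objects or ft not in self.objects:
                raise ValueError(f"morphism {f} has unknown endpoint")
            if self.compose(self.identity[ft], f) != f:
                raise ValueError(f"left identity law fails at {f}")
            if self.compose(f, self.identity[fs]) != f:
                raise ValueError(f"right identity law fails at {f}")
        for g, (gs, gt) in self.morphisms.items():
            for f, (fs, ft) in self.morphisms.items():
                if ft != gs:
                    continue
                gf = self.compose(g, f)
                if self.morphisms[gf] != (fs, gt):
                    raise ValueError(f"composite {g} o {f} mistyped")
                for h, (hs, ht) in self.morphisms.items():
                    if ht != fs:
                        continue
                    if self.compose(gf, h) != self.compose(g, self.compose(f, h)):
                        raise ValueError(
                            f"associativity fails at {g} o {f} o {h}"
                        )


@dataclass
class FunctorMap:
    """Functor between finite categories: object map + morphism map."""

    source: FiniteCategory
    target: FiniteCategory
    object_map: dict
    morphism_map: dict

    def validate(self) -> None:
        for f, (fs, ft) in self.source.morphisms.items():
            Ff = self.morphism_map[f]
            expected = (self.object_map[fs], self.object_map[ft])
            if self.target.morphisms[Ff] != expected:
                raise ValueError(f"functor breaks typing on {f}")
        for obj in self.source.objects:
            if (
                self.morphism_map[self.source.identity[obj]]
                != self.target.identity[self.object_map[obj]]
            ):
                raise ValueError(f"functor breaks identity on {obj}")
        for g in self.source.morphisms:
            for f in self.source.morphisms:
                if self.source.target(f) != self.source.source(g):
                    continue
                if self.morphism_map[self.source.compose(g, f)] != self.target.compose(
                    self.morphism_map[g], self.morphism_map[f]
                ):
                    raise ValueError(f"functor breaks composition on {g} o {f}")


@dataclass
class NaturalTransformationSpec:
    """Component morphisms Φ(M): E(M) → C(M), one per source object."""

    components: dict  # object -> morphism name in the target category


def naturality_check(
    E: FunctorMap, C: FunctorMap, phi: NaturalTransformationSpec
) -> tuple[bool, str | None]:
    """Does C(f) ∘ Φ(M1) = Φ(M2) ∘ E(f) hold for every f: M1 → M2?

    Validates the functor laws first (a broken functor is a precondition
    error, not a naturality failure), checks component typing, then
    tests the commuting square exhaustively; returns the first violating
    morphism as the counterexample.
    """
    if E.source is not C.source or E.target is not C.target:
        raise ValueError("functors must share source and target categories")
    E.validate()
    C.validate()
    tgt = E.target
    for obj in E.source.objects:
        comp = phi.components.get(obj)
        if comp is None:
            raise ValueError(f"missing component at {obj}")
        expected = (E.object_map[obj], C.object_map[obj])
        if tgt.morphisms[comp] != expected:
            raise ValueError(f"component at {obj} mistyped")
    for f, (m1, m2) in E.source.morphisms.items():
        lhs = tgt.compose(C.morphism_map[f], phi.components[m1])
        rhs = tgt.compose(phi.components[m2], E.morphism_map[f])
        if lhs != rhs:
            return False, f
    return True, None


# ---------------------------------------------------------------------------
# finite topology


@dataclass
class FiniteTopology:
    """Finite topological space (X, τ) with a distinguished NC family.

    ``opens`` is the candidate open family τ; ``nc_family`` lists the
    subsets standing for neuronal cells.  Nothing is assumed: the axioms
    are checked and reported by ``topology_check``.
    """

    ground: frozenset
    opens: list  # list[frozenset]
    nc_family: list = field(default_factory=list)


def topology_check(
    space: FiniteTopology,
    quotient_map: Mapping | None = None,
    quotient_target: FiniteTopology | None = None,
) -> dict:
    """Exhaustive axiom report for a finite topological space.

    Checks: τ contains ∅ and X and is closed under (finite) unions and
    intersections; pairwise and total non-emptiness of the NC family's
    intersections; Hausdorff separation checked literally (a finite
    Hausdorff space is necessarily discrete — reported with a warning
    rather than redefined); Lindelöf holds trivially for finite spaces;
    validity of a supplied quotient/identification map (preimages of
    opens are open, map surjective).  Violations carry witnesses.
    """
    X = space.ground
    opens = [frozenset(o) for o in space.opens]
    open_set = set(opens)
    report: dict = {"is_topology": True, "witnesses": {}}

    if frozenset() not in open_set or X not in open_set:
        report["is_topology"] = False
        report["witnesses"]["missing"] = "empty set or ground set not open"
    for a in opens:
        for b in opens:
            if a | b not in open_set:
                report["is_topology"] = False
                report["witnesses"]["union"] = (sorted(a), sorted(b))
            if a & b not in open_set:
                report["is_topology"] = False
                report["witnesses"]["intersection"] = (sorted(a), sorted(b))

    nc = [frozenset(s) for s in space.nc_family]
    if nc:
        total = frozenset(X)
        for s in nc:
            total &= s
        report["nc_total_intersection_nonempty"] = len(total) > 0
        pairwise_ok = True
        for i, a in enumerate(nc):
            for b in nc[i + 1 :]:
                if not a & b:
                    pairwise_ok = False
                    report["witnesses"]["nc_disjoint_pair"] = (sorted(a), sorted(b))
        report["nc_pairwise_intersections_nonempty"] = pairwise_ok

    # Hausdorff, literal check
    hausdorff = True
    witness = None
    for x in X:
        for y in X:
            if x == y:
                continue
            separated = any(
                x in u and y in v and not (u & v)
                for u in opens
                for v in opens
            )
            if not separated:
                hausdorff = False
                witness = (x, y)
                break
        if not hausdorff:
            break
    report["hausdorff"] = hausdorff
    if not hausdorff:
        report["witnesses"]["hausdorff_pair"] = witness
    report["hausdorff_warning"] = (
        "a finite Hausdorff space is discrete; the literal check is reported"
    )
    report["lindelof"] = True  # every finite space is Lindelöf
    report["compact"] = True  # and compact

    if quotient_map is not None:
        if quotient_target is None:
            raise ValueError("quotient check needs the target space")
        surjective = set(quotient_map.values()) >= set(quotient_target.ground)
        preimages_open = True
        for v in quotient_target.opens:
            pre = frozenset(x for x in X if quotient_map[x] in frozenset(v))
            if pre not in open_set:
                preimages_open = False
                report["witnesses"]["quotient_preimage"] = sorted(v)
        report["quotient_map_valid"] = surjective and preimages_open
    return report


# ---------------------------------------------------------------------------
# shape operator


def shape_operator(patch, at: tuple[float, float]):
    """Shape operator S_p(v) = −∇_v N of a parametric patch r(u, v).

    ``patch`` is a triple of sympy expressions in symbols (u, v) (exact
    differentiation) or a callable returning a 3-vector (central
    differences, h = 1e−4).  Returns ``(S, curvatures, directions)``:
    the 2×2 operator in the (r_u, r_v) tangent basis, its eigenvalues
    (principal curvatures, descending) and eigenvectors (principal
    directions as tangent-basis coordinates).
    """
    u0, v0 = at
    if callable(patch):
        h = 1e-4

        def r(u, v):
            return np.asarray(patch(u, v), dtype=float)

        ru = (r(u0 + h, v0) - r(u0 - h, v0)) / (2 * h)
        rv = (r(u0, v0 + h) - r(u0, v0 - h)) / (2 * h)
        ruu = (r(u0 + h, v0) - 2 * r(u0, v0) + r(u0 - h, v0)) / h**2
        rvv = (r(u0, v0 + h) - 2 * r(u0, v0) + r(u0, v0 - h)) / h**2
        ruv = (
            r(u0 + h, v0 + h)
            - r(u0 + h, v0 - h)
            - r(u0 - h, v0 + h)
            + r(u0 - h, v0 - h)
        ) / (4 * h**2)
    else:
        u, v = sympy.symbols("u v")
        rx = sympy.Matrix(
            [sympy.sympify(c, locals={"u": u, "v": v}) for c in patch]
        )
        subs = {u: u0, v: v0}
        ru = np.array(rx.diff(u).subs(subs), dtype=float).ravel()
        rv = np.array(rx.diff(v).subs(subs), dtype=float).ravel()
        ruu = np.array(rx.diff(u, 2).subs(subs), dtype=float).ravel()
        ruv = np.array(rx.diff(u).diff(v).subs(subs), dtype=float).ravel()
        rvv = np.array(rx.diff(v, 2).subs(subs), dtype=float).ravel()

    normal = np.cross(ru, rv)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise ArithmeticError("degenerate first fundamental form (r_u x r_v = 0)")
    N = normal / norm
    E1 = ru @ ru
    F1 = ru @ rv
    G1 = rv @ rv
    if E1 * G1 - F1 * F1 < 1e-18:
        raise ArithmeticError("degenerate metric at the evaluation point")
    L = ruu @ N
    M = ruv @ N
    Nn = rvv @ N
    first = np.array([[E1, F1], [F1, G1]])
    second = np.array([[L, M], [M, Nn]])
    S = np.linalg.solve(first, second)
    eigvals, eigvecs = np.linalg.eig(S)
    order = np.argsort(eigvals.real)[::-1]
    curvatures = eigvals.real[order]
    directions = eigvecs.real[:, order]
    return S, curvatures, directions
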