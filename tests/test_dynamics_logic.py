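"""Van der Pol fields, Gibbs gating, Boolean differentials, forms,
naturality and topology checks, shape operator."""

import itertools
import math

import numpy as np
import pytest

from neuroplate.dynamics_logic import (
    BooleanState,
    FiniteCategory,
    FiniteTopology,
    FunctorMap,
    GibbsState,
    KForm,
    NaturalTransformationSpec,
    VanDerPolParams,
    boolean_max,
    boolean_min,
    boolean_total_differential,
    gated_integral,
    gibbs_differential,
    gibbs_energy,
    growth_gate,
    integrate_van_der_pol,
    kform_eval,
    naturality_check,
    shape_operator,
    single_flip_transitions,
    topology_check,
    van_der_pol_field,
    wedge_eval,
)


class TestVanDerPol:
    def test_printed_substitution(self):
        dx1, dx2 = van_der_pol_field(0.0, 1.0, VanDerPolParams(1.0))
        assert dx2 == 1.0
        assert dx1 == 1.0  # companion equation x1' = x2

    def test_harmonic_limit_conserves_energy(self):
        traj = integrate_van_der_pol(
            (1.0, 0.0), VanDerPolParams(0.0), h=1e-3, steps=6284
        )
        energy = traj[:, 0] ** 2 + traj[:, 1] ** 2
        assert np.max(np.abs(energy - energy[0])) < 1e-3

    def test_small_m_limit_cycle_amplitude(self):
        traj = integrate_van_der_pol(
            (0.1, 0.0), VanDerPolParams(0.1), h=1e-2, steps=20_000
        )
        amplitude = np.max(np.abs(traj[10_000:, 0]))
        assert 1.9 <= amplitude <= 2.1

    def test_trajectories_enter_annulus(self, rng):
        for _ in range(10):
            x0 = rng.uniform(-2.5, 2.5, size=2)
            if np.linalg.norm(x0) < 1e-2:
                x0 += 0.1
            traj = integrate_van_der_pol(x0, VanDerPolParams(1.0), h=1e-2, steps=5000)
            r = np.linalg.norm(traj[3000:], axis=1)
            assert np.all((r > 0.5) & (r < 3.0))

    def test_negative_damping_rejected(self):
        with pytest.raises(ValueError):
            VanDerPolParams(-0.1)


class TestGibbs:
    def test_worked_substitution(self):
        state = GibbsState(U=100.0, p=1.0, V=10.0, T=300.0, S=0.2)
        assert gibbs_energy(state) == pytest.approx(50.0)

    def test_zero_temperature(self):
        state = GibbsState(U=5.0, p=2.0, V=3.0, T=0.0, S=9.0)
        assert gibbs_energy(state) == 11.0

    def test_linearity_in_U(self):
        s1 = GibbsState(U=1.0, p=1.0, V=1.0, T=1.0, S=1.0)
        s2 = GibbsState(U=4.5, p=1.0, V=1.0, T=1.0, S=1.0)
        assert gibbs_energy(s2) - gibbs_energy(s1) == pytest.approx(3.5)

    def test_differential_and_gate(self):
        state = GibbsState(U=0, p=1, V=2, T=300, S=0.1, species=[(-5.0, 1.0)])
        dG, proceed = gibbs_differential(state, 0.0, 0.0, [1.0])
        assert dG == pytest.approx(-5.0) and proceed
        dG0, p0 = gibbs_differential(state, 0.0, 0.0, [0.0])
        assert dG0 == 0.0 and not p0

    def test_additivity_over_species(self):
        base = dict(U=0, p=1, V=1, T=10, S=0.5)
        s_both = GibbsState(**base, species=[(2.0, 0), (-3.0, 0)])
        dG, _ = gibbs_differential(s_both, 0.1, -0.2, [1.0, 2.0])
        s_a = GibbsState(**base, species=[(2.0, 0)])
        s_b = GibbsState(**base, species=[(-3.0, 0)])
        dGa, _ = gibbs_differential(s_a, 0.1, -0.2, [1.0])
        dGb, _ = gibbs_differential(s_b, 0.0, 0.0, [2.0])
        assert dG == pytest.approx(dGa + dGb)

    def test_proceed_antisymmetric_under_negation(self, rng):
        state = GibbsState(
            U=0, p=1, V=2, T=50, S=1.3, species=[(1.7, 0), (-0.4, 0)]
        )
        for _ in range(20):
            dT, dp = rng.normal(size=2)
            dn = rng.normal(size=2)
            dG, fwd = gibbs_differential(state, dT, dp, dn)
            _, bwd = gibbs_differential(state, -dT, -dp, -dn)
            if dG != 0:
                assert fwd != bwd

    def test_species_length_guard(self):
        state = GibbsState(U=0, p=1, V=1, T=1, S=1, species=[(1.0, 0)])
        with pytest.raises(ValueError):
            gibbs_differential(state, 0, 0, [1.0, 2.0])


class TestBooleanDifferential:
    AND = (0, 0, 0, 1)  # little-endian truth table over (X1, X2)

    def test_zero_perturbation(self):
        st = BooleanState((1, 0), (0, 0), self.AND)
        assert boolean_total_differential(st) == 0
        assert boolean_min(st) == boolean_max(st) == st.f(st.X)

    def test_and_gate_worked_example(self):
        st = BooleanState((1, 1), (1, 0), self.AND)
        # f(1,1)=1, f(0,1)=0: d=1, min=0, max=1
        assert boolean_total_differential(st) == 1
        assert boolean_min(st) == 0
        assert boolean_max(st) == 1

    def test_identity_d_equals_max_xor_min_exhaustive_arity2(self):
        failures = 0
        for table_idx in range(16):
            table = tuple((table_idx >> k) & 1 for k in range(4))
            for X in itertools.product((0, 1), repeat=2):
                for dX in itertools.product((0, 1), repeat=2):
                    st = BooleanState(X, dX, table)
                    d = boolean_total_differential(st)
                    if d != (boolean_max(st) ^ boolean_min(st)):
                        failures += 1
        assert failures == 0

    def test_min_le_f_le_max_sampled_arity3(self, rng):
        for _ in range(50):
            table = tuple(int(b) for b in rng.integers(0, 2, 8))
            X = tuple(int(b) for b in rng.integers(0, 2, 3))
            dX = tuple(int(b) for b in rng.integers(0, 2, 3))
            st = BooleanState(X, dX, table)
            assert boolean_min(st) <= st.f(X) <= boolean_max(st)
            assert boolean_total_differential(st) == (
                boolean_max(st) ^ boolean_min(st)
            )

    def test_arity_mismatch(self):
        with pytest.raises(ValueError):
            BooleanState((1,), (1, 0), self.AND)


class TestGrowthGate:
    transitions = single_flip_transitions()

    def test_no_change_gives_zero(self):
        g, log = growth_gate((0, 0, 0), (0, 0, 0), self.transitions)
        assert g == 0 and log["reason"] == "no change"

    def test_admissible_single_flip(self):
        g, log = growth_gate((0, 0, 0), (1, 0, 0), self.transitions)
        assert g == 1

    def test_double_flip_rejected(self):
        g, log = growth_gate((0, 0, 0), (1, 1, 0), self.transitions)
        assert g == 0 and "not in gate graph" in log["reason"]

    def test_gated_integral_accumulates(self):
        steps = [
            ((0, 0, 0), (1, 0, 0)),  # g=1
            ((1, 0, 0), (1, 0, 0)),  # g=0, no change
            ((1, 0, 0), (1, 1, 0)),  # g=1
            ((1, 1, 0), (0, 0, 1)),  # g=0, not an edge
        ]
        total, logs = gated_integral(steps, self.transitions, [2.0, 5.0, 3.0, 7.0], 0.1)
        assert total == pytest.approx(0.5)
        assert [log["g"] for log in logs] == [1, 0, 1, 0]


class TestForms:
    def test_dx_wedge_dy_is_determinant(self):
        dx = KForm(1, 2, {(0,): 1.0})
        dy = KForm(1, 2, {(1,): 1.0})
        assert wedge_eval(dx, dy, [(1, 0), (0, 1)]) == pytest.approx(1.0)
        assert wedge_eval(dx, dy, [(0, 1), (1, 0)]) == pytest.approx(-1.0)

    def test_kform_single_term_determinant(self, rng):
        form = KForm(2, 3, {(0, 1): 1.0})
        v = rng.normal(size=(2, 3))
        expected = np.linalg.det(np.column_stack([v[0][:2], v[1][:2]]))
        assert kform_eval(form, v) == pytest.approx(expected)

    def test_zero_form_coefficients(self):
        form = KForm(2, 3, {})
        assert kform_eval(form, [(1, 0, 0), (0, 1, 0)]) == 0.0

    def test_graded_commutativity(self, rng):
        # alpha ^ beta = (-1)^{kl} beta ^ alpha for seeded 1- and 2-forms in R^3
        for _ in range(20):
            a1 = KForm(1, 3, {(i,): rng.normal() for i in range(3)})
            b1 = KForm(1, 3, {(i,): rng.normal() for i in range(3)})
            v2 = rng.normal(size=(2, 3))
            assert wedge_eval(a1, b1, v2) == pytest.approx(
                (-1) ** (1 * 1) * wedge_eval(b1, a1, v2), abs=1e-12
            )
            a2 = KForm(
                2, 3, {idx: rng.normal() for idx in [(0, 1), (0, 2), (1, 2)]}
            )
            v3 = rng.normal(size=(3, 3))
            assert wedge_eval(a2, b1, v3) == pytest.approx(
                (-1) ** (2 * 1) * wedge_eval(b1, a2, v3), abs=1e-12
            )

    def test_bilinearity(self, rng):
        a = KForm(1, 3, {(i,): rng.normal() for i in range(3)})
        b = KForm(1, 3, {(i,): rng.normal() for i in range(3)})
        u, v, w = rng.normal(size=(3, 3))
        lhs = wedge_eval(a, b, [2.0 * u + w, v])
        rhs = 2.0 * wedge_eval(a, b, [u, v]) + wedge_eval(a, b, [w, v])
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_wedge_matches_kform_of_basis_product(self, rng):
        # (dx0 ^ dx1) as a wedge of basis 1-forms equals the 2-form direct eval
        dx0 = KForm(1, 3, {(0,): 1.0})
        dx1 = KForm(1, 3, {(1,): 1.0})
        direct = KForm(2, 3, {(0, 1): 1.0})
        for _ in range(20):
            v = rng.normal(size=(2, 3))
            assert wedge_eval(dx0, dx1, v) == pytest.approx(
                kform_eval(direct, v), abs=1e-12
            )

    def test_vector_count_guard(self):
        with pytest.raises(ValueError):
            kform_eval(KForm(2, 3, {(0, 1): 1.0}), [(1, 0, 0)])


def _two_object_category():
    objects = frozenset({"M1", "M2"})
    morphisms = {"id1": ("M1", "M1"), "id2": ("M2", "M2"), "f": ("M1", "M2")}
    composition = {
        ("id1", "id1"): "id1",
        ("id2", "id2"): "id2",
        ("f", "id1"): "f",
        ("id2", "f"): "f",
    }
    return FiniteCategory(objects, morphisms, composition, {"M1": "id1", "M2": "id2"})


def _square_category():
    """Commutative square: objects A,B,C,D with two paths A->D."""
    objects = frozenset({"A", "B", "C", "D"})
    morphisms = {
        "idA": ("A", "A"),
        "idB": ("B", "B"),
        "idC": ("C", "C"),
        "idD": ("D", "D"),
        "ab": ("A", "B"),
        "ac": ("A", "C"),
        "bd": ("B", "D"),
        "cd": ("C", "D"),
        "ad": ("A", "D"),
    }
    identity = {o: f"id{o}" for o in objects}
    composition = {}
    for g, (gs, gt) in morphisms.items():
        for f, (fs, ft) in morphisms.items():
            if ft != gs:
                continue
            if f.startswith("id"):
                composition[(g, f)] = g
            elif g.startswith("id"):
                composition[(g, f)] = f
            else:
                composition[(g, f)] = "ad"
    return FiniteCategory(objects, morphisms, composition, identity)


class TestCategories:
    def test_category_validates(self):
        _two_object_category().validate()
        _square_category().validate()

    def test_identity_naturality(self):
        cat = _two_object_category()
        E = FunctorMap(cat, cat, {"M1": "M1", "M2": "M2"},
                       {"id1": "id1", "id2": "id2", "f": "f"})
        phi = NaturalTransformationSpec({"M1": "id1", "M2": "id2"})
        ok, counter = naturality_check(E, E, phi)
        assert ok and counter is None

    def test_naturality_in_square_category(self):
        # E maps the walking arrow to the top path, C to the bottom path;
        # phi components make the square commute by construction
        arrow = _two_object_category()
        sq = _square_category()
        E = FunctorMap(arrow, sq, {"M1": "A", "M2": "B"},
                       {"id1": "idA", "id2": "idB", "f": "ab"})
        C = FunctorMap(arrow, sq, {"M1": "C", "M2": "D"},
                       {"id1": "idC", "id2": "idD", "f": "cd"})
        phi = NaturalTransformationSpec({"M1": "ac", "M2": "bd"})
        ok, counter = naturality_check(E, C, phi)
        assert ok and counter is None

    def test_mismatched_component_detected_with_counterexample(self):
        # components typed correctly but the square cannot commute when
        # C(f) is replaced by an identity path that skips the square
        arrow = _two_object_category()
        sq = _square_category()
        E = FunctorMap(arrow, sq, {"M1": "A", "M2": "B"},
                       {"id1": "idA", "id2": "idB", "f": "ab"})
        C = FunctorMap(arrow, sq, {"M1": "A", "M2": "D"},
                       {"id1": "idA", "id2": "idD", "f": "ad"})
        phi = NaturalTransformationSpec({"M1": "idA", "M2": "bd"})
        ok, counter = naturality_check(E, C, phi)
        # Cf o phi(M1) = ad o idA = ad; phi(M2) o Ef = bd o ab = ad: commutes!
        assert ok
        # now break it: phi(M2) routed through the wrong path object
        phi_bad = NaturalTransformationSpec({"M1": "idA", "M2": "idD"})
        with pytest.raises(ValueError):
            # idD is mistyped as a component E(M2)=B -> C(M2)=D
            naturality_check(E, C, phi_bad)

    def test_parallel_morphisms_expose_failed_square(self):
        # target has two parallel arrows B -> D; E routes f through g1,
        # C through g2, identity components: the square cannot commute
        objects = frozenset({"B", "D"})
        morphisms = {
            "idB": ("B", "B"),
            "idD": ("D", "D"),
            "g1": ("B", "D"),
            "g2": ("B", "D"),
        }
        composition = {
            ("idB", "idB"): "idB",
            ("idD", "idD"): "idD",
            ("g1", "idB"): "g1",
            ("g2", "idB"): "g2",
            ("idD", "g1"): "g1",
            ("idD", "g2"): "g2",
        }
        parallel = FiniteCategory(
            objects, morphisms, composition, {"B": "idB", "D": "idD"}
        )
        arrow = _two_object_category()
        E = FunctorMap(arrow, parallel, {"M1": "B", "M2": "D"},
                       {"id1": "idB", "id2": "idD", "f": "g1"})
        C = FunctorMap(arrow, parallel, {"M1": "B", "M2": "D"},
                       {"id1": "idB", "id2": "idD", "f": "g2"})
        phi = NaturalTransformationSpec({"M1": "idB", "M2": "idD"})
        ok, counter = naturality_check(E, C, phi)
        assert not ok and counter == "f"

    def test_agrees_with_bruteforce_on_fixture_categories(self):
        from neuroplate.io_cli import FixtureKind, FixtureSpec, make_fixtures

        cats = make_fixtures(FixtureSpec(FixtureKind.FINITE_CATEGORIES, 6, seed=3))
        for cat in cats:
            E = FunctorMap(
                cat,
                cat,
                {o: o for o in cat.objects},
                {m: m for m in cat.morphisms},
            )
            phi = NaturalTransformationSpec(
                {o: cat.identity[o] for o in cat.objects}
            )
            ok, _ = naturality_check(E, E, phi)
            # brute force: two-sided composition enumeration
            brute = all(
                cat.compose(E.morphism_map[f], phi.components[cat.source(f)])
                == cat.compose(phi.components[cat.target(f)], E.morphism_map[f])
                for f in cat.morphisms
            )
            assert ok == brute

    def test_functor_law_violation_is_precondition_error(self):
        cat = _two_object_category()
        bad = FunctorMap(cat, cat, {"M1": "M1", "M2": "M2"},
                         {"id1": "id1", "id2": "id2", "f": "id1"})
        phi = NaturalTransformationSpec({"M1": "id1", "M2": "id2"})
        with pytest.raises(ValueError):
            naturality_check(bad, bad, phi)


class TestTopology:
    def test_discrete_topology_on_three_points(self):
        X = frozenset({1, 2, 3})
        opens = [frozenset(s) for s in itertools.chain.from_iterable(
            itertools.combinations([1, 2, 3], r) for r in range(4)
        )]
        report = topology_check(FiniteTopology(X, opens))
        assert report["is_topology"]
        assert report["hausdorff"]
        assert report["lindelof"]

    def test_missing_union_witnessed(self):
        X = frozenset({1, 2, 3})
        opens = [frozenset(), X, frozenset({1}), frozenset({2})]  # {1,2} missing
        report = topology_check(FiniteTopology(X, opens))
        assert not report["is_topology"]
        assert "union" in report["witnesses"]

    def test_indiscrete_space_not_hausdorff(self):
        X = frozenset({1, 2})
        report = topology_check(FiniteTopology(X, [frozenset(), X]))
        assert report["is_topology"]
        assert not report["hausdorff"]
        assert report["witnesses"]["hausdorff_pair"] is not None

    def test_nc_family_intersections(self):
        X = frozenset(range(5))
        opens = [frozenset(), X]
        nc_ok = [frozenset({0, 1, 2}), frozenset({2, 3}), frozenset({2, 4})]
        report = topology_check(FiniteTopology(X, opens, nc_ok))
        assert report["nc_pairwise_intersections_nonempty"]
        assert report["nc_total_intersection_nonempty"]
        nc_bad = [frozenset({0, 1}), frozenset({3, 4})]
        report = topology_check(FiniteTopology(X, opens, nc_bad))
        assert not report["nc_pairwise_intersections_nonempty"]
        assert "nc_disjoint_pair" in report["witnesses"]

    def test_quotient_map_validity(self):
        X = frozenset({1, 2, 3, 4})
        opens = [frozenset(), X, frozenset({1, 2}), frozenset({3, 4})]
        space = FiniteTopology(X, opens)
        Y = frozenset({"a", "b"})
        target = FiniteTopology(
            Y, [frozenset(), Y, frozenset({"a"}), frozenset({"b"})]
        )
        qmap = {1: "a", 2: "a", 3: "b", 4: "b"}
        report = topology_check(space, qmap, target)
        assert report["quotient_map_valid"]
        bad_map = {1: "a", 2: "b", 3: "b", 4: "b"}  # preimage of {a} = {1} not open
        report = topology_check(space, bad_map, target)
        assert not report["quotient_map_valid"]


class TestShapeOperator:
    def test_unit_sphere_curvatures(self):
        patch = (
            "cos(u)*cos(v)",
            "sin(u)*cos(v)",
            "sin(v)",
        )
        _, curvatures, _ = shape_operator(patch, (0.3, 0.4))
        np.testing.assert_allclose(np.abs(curvatures), [1.0, 1.0], atol=1e-8)

    def test_cylinder_curvatures(self):
        r = 2.0
        patch = (f"{r}*cos(u)", f"{r}*sin(u)", "v")
        _, curvatures, _ = shape_operator(patch, (0.5, 1.0))
        np.testing.assert_allclose(
            sorted(np.abs(curvatures)), [0.0, 1.0 / r], atol=1e-8
        )

    def test_plane_is_flat(self):
        patch = ("u", "v", "2*u + 3*v + 1")
        _, curvatures, _ = shape_operator(patch, (0.2, -0.7))
        np.testing.assert_allclose(curvatures, [0.0, 0.0], atol=1e-8)

    def test_matches_normal_derivative_oracle_on_quadratic_patch(self, rng):
        # S_p(v) = -d/ds N(u + s v1, v + s v2) in the tangent basis
        c = rng.normal(size=3) * 0.3

        def patch(u, v):
            return np.array([u, v, c[0] * u * u + c[1] * u * v + c[2] * v * v])

        at = (0.1, -0.2)
        S, _, _ = shape_operator(patch, at)

        def normal(u, v):
            h = 1e-5
            ru = (patch(u + h, v) - patch(u - h, v)) / (2 * h)
            rv = (patch(u, v + h) - patch(u, v - h)) / (2 * h)
            n = np.cross(ru, rv)
            return n / np.linalg.norm(n)

        h = 1e-4
        for direction in (np.array([1.0, 0.0]), np.array([0.0, 1.0])):
            dN = (
                normal(at[0] + h * direction[0], at[1] + h * direction[1])
                - normal(at[0] - h * direction[0], at[1] - h * direction[1])
            ) / (2 * h)
            # express -dN in the tangent basis (r_u, r_v) by least squares
            hp = 1e-5
            ru = (patch(at[0] + hp, at[1]) - patch(at[0] - hp, at[1])) / (2 * hp)
            rv = (patch(at[0], at[1] + hp) - patch(at[0], at[1] - hp)) / (2 * hp)
            basis = np.column_stack([ru, rv])
            coords, *_ = np.linalg.lstsq(basis, -dN, rcond=None)
            np.testing.assert_allclose(coords, S @ direction, atol=1e-5)

    def test_degenerate_patch_raises(self):
        patch = ("u", "u", "0*v + u")  # r_u parallel to itself, r_v = 0
        with pytest.raises(ArithmeticError):
            shape_operator(patch, (0.1, 0.1))
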