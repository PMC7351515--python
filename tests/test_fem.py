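"""Finite-element kernel and solver tests.

The two structural oracles are (1) internal force = finite-difference
gradient of the element energy, and (2) assembled tangent =
finite-difference Jacobian of the global residual; both are independent
of the analytic implementation they check.
"""

import numpy as np
import pytest

from myofem.fem import (
    BoundaryConditions,
    FemModel,
    Phase,
    SolverError,
    SolverParams,
    green_lagrange,
    newton_solve,
    spring_force,
)
from myofem.geometry import (
    GeometryParams,
    LinkParams,
    SpringLink,
    add_fiber_matrix_links,
    build_muscle_mesh,
)
from myofem.materials import MaterialParams, fiber_pk2_stress
from myofem.verify import (
    check_energy_gradient,
    check_tangent_consistency,
    make_single_hex_model,
    max_volume_deviation_pct,
    solve_uniaxial_stretch,
)


class TestKinematics:
    @pytest.mark.parametrize(
        "F, expected",
        [
            (np.eye(3), np.zeros((3, 3))),
            (np.diag([1.2, 1.0, 1.0]), np.diag([0.22, 0.0, 0.0])),
            (
                np.array([[1.0, 0.1, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]),
                np.array([[0.0, 0.05, 0.0], [0.05, 0.005, 0.0], [0.0, 0.0, 0.0]]),
            ),
        ],
    )
    def test_green_lagrange_closed_forms(self, F, expected):
        assert np.allclose(green_lagrange(F), expected, atol=1e-14)


class TestElementForces:
    def test_zero_displacement_passive_gives_zero_force(self):
        for family in ("ecm", "myofiber", "aponeurosis"):
            model = make_single_hex_model(family=family)
            fam = model.families[family]
            f = fam.force(np.zeros((1, 8, 3)), b3=0.0)
            assert np.allclose(f, 0.0, atol=1e-14)

    def test_force_is_energy_gradient_on_random_states(self):
        errors = check_energy_gradient(seed=11, n_states=100)
        for family, err in errors.items():
            assert err <= 1e-6, family

    def test_activated_fiber_element_end_face_resultant(self):
        """A fully activated element at zero strain pulls its end faces
        together with the uniaxial stress resultant (stress x area)."""
        model = make_single_hex_model(family="myofiber")
        fam = model.families["myofiber"]
        f = fam.force(np.zeros((1, 8, 3)), b3=1.0)[0]
        bottom = np.flatnonzero(np.isclose(model.mesh.nodes[:, 1], 0.0))
        resultant = f[bottom, 1].sum()
        expected = float(fiber_pk2_stress(0.0, 1.0))  # x unit face area
        assert resultant == pytest.approx(-expected, rel=1e-12)
        assert f[bottom, 1].sum() == pytest.approx(-f[~np.isin(np.arange(8), bottom), 1].sum())

    def test_homogeneous_deformation_face_traction_oracle(self):
        """Under a prescribed uniform F the summed face forces equal the
        closed-form PK1 traction times the reference face area."""
        from myofem.materials import EcmParams, ecm_anisotropic_stress

        model = make_single_hex_model(family="ecm")
        fam = model.families["ecm"]
        F = np.diag([1.05, 1.1, 0.9])
        u_e = (model.mesh.nodes @ F.T - model.mesh.nodes)[None]
        f = fam.force(u_e, 0.0)[0]
        # independent closed form: local frame is identity here
        E = green_lagrange(F)
        S = ecm_anisotropic_stress(E, EcmParams())
        C = F.T @ F
        I3 = np.linalg.det(C)
        p = EcmParams()
        S = S + 4 * (p.Ss + p.Sf) * (I3 - 1) * I3 * np.linalg.inv(C)
        P = F @ S
        top = np.isclose(model.mesh.nodes[:, 1], 1.0)
        assert np.allclose(f[top].sum(axis=0), P @ [0, 1, 0], rtol=1e-9)


class TestSprings:
    def test_zero_elongation_zero_force(self):
        ln = SpringLink(kind="extramuscular", node_a=0, anchor=np.zeros(3), stiffness=0.25)
        nodes = np.zeros((1, 3))
        f_a, f_b = spring_force(ln, nodes, np.zeros((1, 3)))
        assert np.allclose(f_a, 0.0)

    def test_unit_elongation_at_stated_stiffness(self):
        ln = SpringLink(kind="extramuscular", node_a=0, anchor=np.zeros(3), stiffness=0.25)
        nodes = np.zeros((1, 3))
        u = np.array([[1.0, 0.0, 0.0]])
        f_a, _ = spring_force(ln, nodes, u)
        assert np.linalg.norm(f_a) == pytest.approx(0.25)
        f2, _ = spring_force(ln, nodes, 2 * u)
        assert np.allclose(f2, 2 * f_a)

    def test_pair_link_forces_equal_and_opposite(self):
        ln = SpringLink(kind="fiber_matrix", node_a=0, node_b=1, stiffness=5.0)
        nodes = np.zeros((2, 3))
        u = np.array([[0.0, 0.0, 0.0], [0.3, -0.1, 0.2]])
        f_a, f_b = spring_force(ln, nodes, u)
        assert np.allclose(f_a, -f_b)
        assert np.allclose(f_a, 5.0 * u[1])


class TestAssembly:
    def test_tangent_matches_residual_finite_difference(self):
        assert check_tangent_consistency(seed=7) <= 1e-5

    def test_rigid_translation_gives_zero_residual(self, geometry, links):
        mesh = add_fiber_matrix_links(build_muscle_mesh(geometry), links)
        model = FemModel(mesh, MaterialParams())
        u = np.tile([1.7, -0.6, 0.4], (mesh.n_nodes, 1))
        R = model.residual(u, b3=0.0)
        assert np.abs(R).max() < 1e-9

    def test_internal_forces_sum_to_zero_per_axis(self, rng):
        g = GeometryParams(
            n_series=2, n_parallel=2, initial_length=10.0, pennation_offset=2.0,
            tendon_arm=0.5,
            contour_top=((0.0, 2.0), (1.0, 2.0)),
            contour_bottom=((0.0, 0.0), (1.0, 0.0)),
        )
        mesh = add_fiber_matrix_links(build_muscle_mesh(g), LinkParams())
        model = FemModel(mesh, MaterialParams())
        u = rng.uniform(-0.05, 0.05, size=(mesh.n_nodes, 3))
        R = model.residual(u, b3=0.7)
        assert np.allclose(R.sum(axis=0), 0.0, atol=1e-10)


class TestNewtonSolver:
    def test_fixed_ends_at_reference_stay_at_reference(self):
        model, sol = _solve_clamped_reference()
        assert sol.converged
        assert np.abs(sol.displacement).max() < 1e-10

    def test_rigid_translation_produces_no_strain(self, geometry, links):
        mesh = add_fiber_matrix_links(build_muscle_mesh(geometry), links)
        model = FemModel(mesh, MaterialParams())
        bc = BoundaryConditions.empty(mesh.n_nodes)
        ends = np.concatenate(
            [mesh.node_sets["proximal_end"], mesh.node_sets["distal_end"]]
        )
        bc.prescribe(ends)
        v0 = np.zeros((mesh.n_nodes, 3))
        v1 = v0.copy()
        v1[ends, 0] = 2.0
        sol = newton_solve(model, bc, [Phase(v0, v1, 0, 0, 2, "shift")])
        st = model.strain_state("myofiber", sol.displacement)
        assert np.abs(st["E"]).max() < 1e-9

    def test_single_element_stretch_reaction_matches_uniaxial_resultant(self):
        """Reaction on the stretched face equals the PK1 resultant of the
        element's own (near-uniform) converged stress state."""
        from myofem.materials import EcmParams, ecm_anisotropic_stress

        model, sol = solve_uniaxial_stretch(0.10, steps=2)
        fam = model.families["ecm"]
        st = fam.strain_state(sol.displacement[fam.conn])
        p = EcmParams()
        S = ecm_anisotropic_stress(st["E_local"], p)
        S = 0.5 * (S + np.eye(3) * S)
        I3 = st["I3"]
        I3avg = (fam.dV * I3).sum() / fam.Ve
        S = S + (4 * (p.Ss * (I3 - 1) + p.Sf * (I3avg - 1)) * I3)[..., None, None] * np.linalg.inv(st["C"])
        P = np.einsum("egik,egkj->egij", st["F"], S)
        expected = P[0, :, 1, 1].mean()  # mean PK1 traction x unit area
        top = np.flatnonzero(np.isclose(model.mesh.nodes[:, 1], 1.0))
        reaction = sol.reactions[top, 1].sum()
        assert reaction == pytest.approx(expected, rel=1e-6)

    def test_volume_nearly_conserved_at_large_stretch(self):
        model, sol = solve_uniaxial_stretch(0.45)
        assert max_volume_deviation_pct(model, sol.displacement) < 5.0

    def test_unconstrained_model_raises_diagnostic(self):
        # an activated free-floating element has rigid-body modes and a
        # nonzero residual: the solver must fail with a diagnostic
        model = make_single_hex_model(family="myofiber")
        bc = BoundaryConditions.empty(8)  # nothing prescribed at all
        v = np.zeros((8, 3))
        with pytest.raises(SolverError, match="unconstrained|singular|convergence"):
            newton_solve(model, bc, [Phase(v, v, 0.0, 1.0, 1, "x")],
                         SolverParams(max_bisections=0))


def _solve_clamped_reference():
    g = GeometryParams(
        n_series=2, n_parallel=2, initial_length=10.0, pennation_offset=2.0,
        tendon_arm=0.5,
        contour_top=((0.0, 2.0), (1.0, 2.0)),
        contour_bottom=((0.0, 0.0), (1.0, 0.0)),
    )
    mesh = add_fiber_matrix_links(build_muscle_mesh(g), LinkParams())
    model = FemModel(mesh, MaterialParams())
    bc = BoundaryConditions.empty(mesh.n_nodes)
    ends = np.concatenate([mesh.node_sets["proximal_end"], mesh.node_sets["distal_end"]])
    bc.prescribe(ends)
    v = np.zeros((mesh.n_nodes, 3))
    sol = newton_solve(model, bc, [Phase(v, v, 0.0, 0.0, 1, "hold")])
    return model, sol
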