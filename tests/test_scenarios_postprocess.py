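"""Scenario protocols and post-processing behaviour.

These tests exercise the full pipeline on the default muscle and assert
the mechanical bookkeeping: length control, grid completeness, load
normalization, global force balance and frame-invariance of reports.
"""

import numpy as np
import pandas as pd
import pytest

from myofem.fem import SolutionState
from myofem.geometry import GeometryParams
from myofem.postprocess import (
    FACES,
    fiber_strain_report,
    myofascial_load_report,
    nodal_fiber_strains,
    proximo_distal_balance,
)
from myofem.scenarios import CaseResult, ScenarioSpec, run_case, stiffness_sweep


def end_to_end(result):
    mesh, u = result.mesh, result.solution.displacement
    prox = (mesh.nodes + u)[mesh.node_sets["proximal_end"], 0].mean()
    dist = (mesh.nodes + u)[mesh.node_sets["distal_end"], 0].mean()
    return dist - prox


class TestProtocols:
    def test_case_i_conserves_muscle_length(self, scenario):
        for variant in ("isolated", "extramuscular", "epimuscular"):
            res = scenario(variant, "I")
            assert end_to_end(res) == pytest.approx(28.7, abs=1e-9)

    def test_case_ii_lengthens_distally_by_two_mm(self, scenario):
        res = scenario("isolated", "II")
        assert end_to_end(res) == pytest.approx(30.7, abs=1e-9)

    def test_case_iii_is_isometric_and_fully_activated(self, scenario):
        res = scenario("isolated", "III")
        assert res.solution.activation == pytest.approx(1.0)
        assert end_to_end(res) == pytest.approx(28.7, abs=1e-9)

    def test_epimuscular_synergist_held_at_reference_length(self, scenario):
        res = scenario("epimuscular", "I")
        mesh, u = res.mesh, res.solution.displacement
        for name in ("syn_proximal_end", "syn_distal_end"):
            assert np.abs(u[mesh.node_sets[name]]).max() < 1e-12

    def test_sweep_requires_connected_variant(self):
        with pytest.raises(ValueError, match="connected"):
            stiffness_sweep(ScenarioSpec(model_variant="isolated", case="II"), [1.0])


class TestStrainReport:
    def test_grid_is_complete_and_finite(self, scenario):
        rep = fiber_strain_report(scenario("isolated", "II"))
        assert rep.grid.shape == (2, 4, 17)
        assert np.all(np.isfinite(rep.grid))
        df = rep.to_dataframe()
        assert len(df) == 136
        assert set(df["face"]) == set(FACES)

    def test_reference_passive_state_reports_zero(self, scenario):
        rep = fiber_strain_report(scenario("isolated", "I"))
        assert np.abs(rep.grid).max() < 1e-9

    def test_manufactured_uniform_stretch_recovers_closed_form(self):
        """A 10% fiber-direction stretch imposed on an unpennated bar
        reports the Green-Lagrange value (lambda^2 - 1)/2 = 0.105
        in every grid cell."""
        from myofem.fem import FemModel
        from myofem.geometry import add_fiber_matrix_links, build_muscle_mesh, LinkParams
        from myofem.materials import MaterialParams

        g = GeometryParams(
            n_series=3, n_parallel=4, initial_length=10.0, pennation_offset=0.0,
            tendon_arm=0.4,
            contour_top=((0.0, 3.0), (1.0, 3.0)),
            contour_bottom=((0.0, 0.0), (1.0, 0.0)),
        )
        mesh = add_fiber_matrix_links(build_muscle_mesh(g), LinkParams())
        model = FemModel(mesh, MaterialParams())
        u = np.zeros((mesh.n_nodes, 3))
        u[:, 1] = 0.1 * mesh.nodes[:, 1]  # fibers run along Y here
        sol = SolutionState(u, 0.0, True, 0.0, np.zeros_like(u))
        res = CaseResult(
            ScenarioSpec(), mesh, model, sol, g, LinkParams(), MaterialParams()
        )
        rep = fiber_strain_report(res)
        assert np.allclose(rep.grid, 0.105, atol=1e-12)

    def test_unconverged_solution_is_refused(self, scenario):
        res = scenario("isolated", "I")
        bad = CaseResult(
            res.spec, res.mesh, res.model,
            SolutionState(res.solution.displacement, 0.0, False, 0.1,
                          res.solution.reactions),
            res.geometry, res.links, res.materials,
        )
        with pytest.raises(ValueError, match="converge"):
            fiber_strain_report(bad)

    def test_report_invariant_to_rigid_translation(self, scenario):
        res = scenario("isolated", "II")
        base = nodal_fiber_strains(res.model, res.solution.displacement)
        shifted = nodal_fiber_strains(
            res.model, res.solution.displacement + np.array([0.9, -0.4, 0.2])
        )
        assert np.allclose(base, shifted, atol=1e-10)

    def test_percent_output_rounded_to_reporting_precision(self, scenario):
        df = fiber_strain_report(scenario("isolated", "II")).to_dataframe()
        assert np.allclose(df["strain_pct"], np.round(df["strain_pct"], 1))


class TestLoadReport:
    def test_isolated_variant_yields_empty_report(self, scenario):
        reps = myofascial_load_report({c: scenario("isolated", c) for c in "I"})
        assert reps["I"].empty

    def test_normalization_spans_the_three_cases(self, scenario):
        reps = myofascial_load_report(
            {c: scenario("extramuscular", c) for c in ("I", "II", "III")}
        )
        norms = {c: reps[c].table["normalized"].abs().max() for c in reps}
        assert max(norms.values()) == pytest.approx(1.0)
        assert norms["II"] == pytest.approx(1.0)
        assert np.all(np.abs(pd.concat([r.table for r in reps.values()])["normalized"]) <= 1.0)

    def test_renormalization_is_idempotent(self, scenario):
        results = {c: scenario("extramuscular", c) for c in ("I", "II", "III")}
        first = myofascial_load_report(results)
        second = myofascial_load_report(results)
        for c in first:
            pd.testing.assert_frame_equal(first[c].table, second[c].table)

    def test_mixed_variants_rejected(self, scenario):
        with pytest.raises(ValueError, match="variant"):
            myofascial_load_report(
                {"I": scenario("isolated", "I"), "II": scenario("extramuscular", "II")}
            )


class TestForceBalance:
    def test_isolated_end_reactions_equal_and_opposite(self, scenario):
        for case in ("II", "III"):
            bal = proximo_distal_balance(scenario("isolated", case))
            assert bal.reaction_difference == pytest.approx(0.0, abs=5e-3 * bal.max_reaction)

    def test_connected_difference_equals_net_axial_link_force(self, scenario):
        for variant in ("extramuscular", "epimuscular"):
            bal = proximo_distal_balance(scenario(variant, "II"))
            assert abs(bal.net_link_axial) > 0.1  # loads are actually present
            assert bal.closure <= 5e-3 * bal.max_reaction

    def test_zero_stiffness_sweep_recovers_isolated_balance(self, sweep):
        bal = proximo_distal_balance(sweep("II", 0.0))
        assert bal.net_link_axial == pytest.approx(0.0, abs=1e-12)
        assert bal.reaction_difference == pytest.approx(0.0, abs=5e-3 * bal.max_reaction)
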