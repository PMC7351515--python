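"""Executable boundary-condition protocols.

Three model variants (isolated, extramuscularly connected, epimuscularly
connected pair) crossed with three cases:

* **Case I** — passive isometric muscle with an imposed relative position
  change: both tendon ends of the target muscle displaced distally by
  ``end_shift`` (muscle length unchanged).
* **Case II** — passive lengthened muscle: the Case I position change
  followed by a further ``extra_lengthening`` of the distal end only.
* **Case III** — active isometric muscle with imposed relative position
  change: the Case I shift applied passively, then activation ramped
  from 0 to ``activation_target`` in fixed increments.

For the epimuscular variant the synergist's ends are held fixed at the
reference length throughout; both muscles are grounded extramuscularly
on their lateral faces and interlinked medially.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fem import (
    BoundaryConditions,
    FemModel,
    Phase,
    SolutionState,
    SolverError,
    SolverParams,
    newton_solve,
)
from .geometry import (
    GeometryParams,
    LinkParams,
    MuscleMesh,
    add_fiber_matrix_links,
    attach_extramuscular,
    build_epimuscular_pair,
    build_muscle_mesh,
)
from .materials import MaterialParams

__all__ = ["ScenarioSpec", "CaseResult", "build_variant_mesh", "run_case", "stiffness_sweep"]

VARIANTS = ("isolated", "extramuscular", "epimuscular")
CASES = ("I", "II", "III")


@dataclass
class ScenarioSpec:
    """Model variant x loading case with its protocol parameters (mm)."""

    model_variant: str = "isolated"
    case: str = "I"
    end_shift: float = 2.0
    extra_lengthening: float = 2.0
    activation_target: float = 1.0
    synergist_activated: bool = True

    def validate(self) -> list[str]:
        problems = []
        if self.model_variant not in VARIANTS:
            problems.append(f"scenario.model_variant must be one of {VARIANTS}")
        if self.case not in CASES:
            problems.append(f"scenario.case must be one of {CASES}")
        if not 0.0 <= self.activation_target <= 1.0:
            problems.append("scenario.activation_target must be in [0, 1]")
        return problems


@dataclass
class CaseResult:
    """A solved scenario: mesh + model + converged solution."""

    spec: ScenarioSpec
    mesh: MuscleMesh
    model: FemModel
    solution: SolutionState
    geometry: GeometryParams
    links: LinkParams
    materials: MaterialParams


def build_variant_mesh(variant: str, g: GeometryParams, lp: LinkParams) -> MuscleMesh:
    """Mesh + links for one model variant.

    The isolated variant carries fiber-matrix links only; the
    extramuscular variant adds 17 grounded links on the lateral face;
    the epimuscular variant is the two-muscle assembly.
    """
    if variant == "isolated":
        mesh = build_muscle_mesh(g)
        add_fiber_matrix_links(mesh, lp)
    elif variant == "extramuscular":
        mesh = build_muscle_mesh(g)
        add_fiber_matrix_links(mesh, lp)
        attach_extramuscular(mesh, lp, face="lateral")
    elif variant == "epimuscular":
        mesh = build_epimuscular_pair(g, lp)
    else:
        raise ValueError(f"unknown model variant {variant!r}")
    return mesh


def _activation_mask(mesh: MuscleMesh, spec: ScenarioSpec) -> np.ndarray:
    mask = np.ones(len(mesh.myofiber_elements))
    if mesh.is_pair and not spec.synergist_activated:
        mask[mesh.myofiber_muscle == 1] = 0.0
    return mask


def _phases(mesh: MuscleMesh, bc: BoundaryConditions, spec: ScenarioSpec,
            sp: SolverParams) -> list[Phase]:
    n = mesh.n_nodes
    v0 = np.zeros((n, 3))
    v_shift = v0.copy()
    ends = np.concatenate([mesh.node_sets["proximal_end"], mesh.node_sets["distal_end"]])
    v_shift[ends, 0] = spec.end_shift
    phases = [Phase(v0, v_shift, 0.0, 0.0, sp.displacement_steps, "position shift")]
    if spec.case == "II":
        v_len = v_shift.copy()
        v_len[mesh.node_sets["distal_end"], 0] += spec.extra_lengthening
        phases.append(
            Phase(v_shift, v_len, 0.0, 0.0, sp.displacement_steps, "distal lengthening")
        )
    elif spec.case == "III":
        phases.append(
            Phase(v_shift, v_shift, 0.0, spec.activation_target,
                  sp.activation_steps, "activation ramp")
        )
    return phases


def run_case(
    spec: ScenarioSpec,
    g: GeometryParams | None = None,
    lp: LinkParams | None = None,
    params: MaterialParams | None = None,
    solver: SolverParams | None = None,
    mesh: MuscleMesh | None = None,
) -> CaseResult:
    """Solve one scenario and return the converged state.

    A prebuilt ``mesh`` may be passed to reuse geometry across cases.
    """
    g = g or GeometryParams()
    lp = lp or LinkParams()
    params = params or MaterialParams()
    solver = solver or SolverParams()
    problems = spec.validate() + g.validate() + lp.validate() + params.validate()
    if problems:
        raise ValueError("; ".join(problems))

    if mesh is None:
        mesh = build_variant_mesh(spec.model_variant, g, lp)
    model = FemModel(mesh, params, activation_mask=_activation_mask(mesh, spec))

    bc = BoundaryConditions.empty(mesh.n_nodes)
    bc.prescribe(mesh.node_sets["proximal_end"])
    bc.prescribe(mesh.node_sets["distal_end"])
    if mesh.is_pair:
        bc.prescribe(mesh.node_sets["syn_proximal_end"])
        bc.prescribe(mesh.node_sets["syn_distal_end"])

    phases = _phases(mesh, bc, spec, solver)
    try:
        sol = newton_solve(model, bc, phases, solver)
    except SolverError as err:
        raise SolverError(
            f"{spec.model_variant} Case {spec.case}: {err}"
        ) from err
    return CaseResult(spec, mesh, model, sol, g, lp, params)


def _scaled_links(lp: LinkParams, factor: float) -> LinkParams:
    """Scale the epimuscular (extra- + intermuscular) stiffnesses only."""
    return replace(
        lp,
        k_extra_stiff=lp.k_extra_stiff * factor,
        k_extra_compliant=lp.k_extra_compliant * factor,
        k_inter=lp.k_inter * factor,
    )


def stiffness_sweep(
    spec: ScenarioSpec,
    factors,
    g: GeometryParams | None = None,
    lp: LinkParams | None = None,
    params: MaterialParams | None = None,
    solver: SolverParams | None = None,
) -> list[CaseResult]:
    """Re-run a connected scenario with scaled epimuscular stiffnesses.

    Factor 0 reduces the connected model to isolated mechanics (links
    transmit nothing); larger factors emphasize the strains that oppose
    the globally imposed length change.
    """
    if spec.model_variant == "isolated":
        raise ValueError("stiffness sweep requires a connected model variant")
    g = g or GeometryParams()
    lp = lp or LinkParams()
    results = []
    for f in factors:
        if f == 0.0:
            # zero-stiffness epimuscular links transmit nothing: drop them
            # (keeps the tangent regular) but keep the same mesh topology
            mesh = build_variant_mesh(spec.model_variant, g, lp)
            for ln in mesh.links:
                if ln.kind in ("extramuscular", "intermuscular"):
                    ln.stiffness = 0.0
            mesh.links = [ln for ln in mesh.links if ln.stiffness > 0.0]
            results.append(run_case(spec, g, lp, params, solver, mesh=mesh))
        else:
            results.append(run_case(spec, g, _scaled_links(lp, f), params, solver))
    return results
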