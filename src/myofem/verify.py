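"""Verification rigs and invariant checks.

Small self-contained models (single elements, tiny meshes) used by the
test suite, the ``verify`` CLI subcommand and the acceptance script:
energy-gradient and tangent consistency oracles, and the single-element
volume-conservation rig for the ECM penalty formulation.
"""

from __future__ import annotations

import numpy as np

from .fem import (
    BoundaryConditions,
    FemModel,
    Phase,
    SolverParams,
    newton_solve,
)
from .geometry import HEX_CORNERS, GeometryParams, MuscleMesh
from .materials import MaterialParams

__all__ = [
    "make_single_hex_model",
    "solve_uniaxial_stretch",
    "max_volume_deviation_pct",
    "check_energy_gradient",
    "check_tangent_consistency",
    "run_all_checks",
]


def _cube_nodes(size: float = 1.0) -> np.ndarray:
    return 0.5 * size * (HEX_CORNERS + 1.0)


def make_single_hex_model(
    params: MaterialParams | None = None,
    family: str = "ecm",
    size: float = 1.0,
    n_copies: int = 1,
) -> FemModel:
    """A unit-cube element of one family; local frame = global axes
    (fiber direction along global Y).  ``n_copies`` stacks independent
    copies of the same element for batched randomized checks."""
    params = params or MaterialParams()
    nodes = _cube_nodes(size)
    conn = np.tile(np.arange(8), (n_copies, 1))
    frames = np.tile(np.eye(3), (n_copies, 1, 1))
    empty = np.zeros((0, 8), dtype=int)
    eframes = np.zeros((0, 3, 3))
    mesh = MuscleMesh(
        nodes=nodes,
        ecm_elements=conn if family == "ecm" else empty,
        myofiber_elements=conn if family == "myofiber" else empty,
        apo_elements=conn if family == "aponeurosis" else empty,
        ecm_frames=frames if family == "ecm" else eframes,
        myofiber_frames=frames if family == "myofiber" else eframes,
        fascicle_grid=np.zeros((2, 1, 1), dtype=int),
        matrix_grid=np.zeros((2, 1, 1), dtype=int),
        node_sets={},
        n_series=1,
        n_parallel=1,
        slice_thickness=size,
    )
    return FemModel(mesh, params)


def solve_uniaxial_stretch(
    stretch: float = 0.45,
    params: MaterialParams | None = None,
    family: str = "ecm",
    steps: int = 6,
):
    """Stretch a single element along its fiber (Y) axis.

    The fiber-direction displacement is prescribed on both end faces;
    the lateral faces are free (only rigid-body modes are pinned), so
    the element necks down as the volume penalty demands.
    """
    model = make_single_hex_model(params, family=family)
    mesh = model.mesh
    bot = np.flatnonzero(np.isclose(mesh.nodes[:, 1], 0.0))
    top = np.flatnonzero(np.isclose(mesh.nodes[:, 1], mesh.nodes[:, 1].max()))
    bc = BoundaryConditions.empty(mesh.n_nodes)
    bc.prescribe(bot, axis=1, value=0.0)
    bc.prescribe(top, axis=1, value=0.0)  # target set via phase values
    bc.prescribe([0], axis=0)
    bc.prescribe([0], axis=2)
    bc.prescribe([1], axis=2)
    v0 = np.zeros((mesh.n_nodes, 3))
    v1 = v0.copy()
    v1[top, 1] = stretch * mesh.nodes[:, 1].max()
    sp = SolverParams(displacement_steps=steps)
    sol = newton_solve(model, bc, [Phase(v0, v1, 0.0, 0.0, steps, "stretch")], sp)
    return model, sol


def max_volume_deviation_pct(model: FemModel, u: np.ndarray, family: str = "ecm") -> float:
    """Max over Gauss points of |local volume ratio - 1| in percent."""
    st = model.strain_state(family, u)
    return float(np.max(np.abs(st["I3"] - 1.0)) * 100.0)


def check_energy_gradient(
    seed: int = 0,
    n_states: int = 100,
    scale: float = 0.15,
    b3: float = 1.0,
    h: float = 1e-6,
) -> dict[str, float]:
    """Max relative error between each family's internal force and the
    central finite difference of its element energy, over randomized
    nodal displacement states."""
    rng = np.random.default_rng(seed)
    out = {}
    for family in ("ecm", "myofiber", "aponeurosis"):
        model = make_single_hex_model(family=family, n_copies=n_states)
        fam = model.families[family]
        u_e = rng.uniform(-scale, scale, size=(n_states, 8, 3))
        f = fam.force(u_e, b3)
        fd = np.empty_like(f)
        for a in range(8):
            for i in range(3):
                up = u_e.copy(); up[:, a, i] += h
                um = u_e.copy(); um[:, a, i] -= h
                fd[:, a, i] = (fam.energy(up, b3) - fam.energy(um, b3)) / (2 * h)
        denom = np.maximum(np.abs(f).max(axis=(1, 2)), 1e-3)
        out[family] = float(np.max(np.abs(f - fd).max(axis=(1, 2)) / denom))
    return out


def check_tangent_consistency(seed: int = 0, scale: float = 0.02, h: float = 1e-6) -> float:
    """Assembled tangent vs. finite difference of the global residual on
    a small two-by-two muscle mesh with links (relative max error)."""
    from .geometry import LinkParams, add_fiber_matrix_links, attach_extramuscular
    from .geometry import build_muscle_mesh

    g = GeometryParams(n_series=2, n_parallel=2, initial_length=10.0,
                       pennation_offset=1.0,
                       contour_top=((0.0, 3.0), (0.5, 3.2), (1.0, 3.0)),
                       contour_bottom=((0.0, 0.0), (0.5, 0.1), (1.0, 0.0)))
    lp = LinkParams()
    mesh = build_muscle_mesh(g)
    add_fiber_matrix_links(mesh, lp)
    attach_extramuscular(mesh, lp)
    model = FemModel(mesh, MaterialParams())
    rng = np.random.default_rng(seed)
    u = rng.uniform(-scale, scale, size=(mesh.n_nodes, 3))
    K = model.tangent(u, b3=0.5).toarray()
    Kfd = np.empty_like(K)
    uf = u.ravel().copy()
    for d in range(model.ndof):
        up = uf.copy(); up[d] += h
        um = uf.copy(); um[d] -= h
        col = (
            model.residual(up.reshape(-1, 3), 0.5)
            - model.residual(um.reshape(-1, 3), 0.5)
        ).ravel() / (2 * h)
        Kfd[:, d] = col
    return float(np.max(np.abs(K - Kfd)) / np.max(np.abs(Kfd)))


def run_all_checks(seed: int = 0) -> dict[str, dict]:
    """Invariant suite for the ``verify`` subcommand."""
    results = {}
    grad = check_energy_gradient(seed=seed)
    for fam, err in grad.items():
        results[f"energy_gradient_{fam}"] = {
            "value": err, "threshold": 1e-6, "passed": err <= 1e-6,
        }
    terr = check_tangent_consistency(seed=seed)
    results["tangent_fd"] = {"value": terr, "threshold": 1e-5, "passed": terr <= 1e-5}
    model, sol = solve_uniaxial_stretch(0.45)
    dev = max_volume_deviation_pct(model, sol.displacement)
    results["volume_deviation_pct_at_45pct_stretch"] = {
        "value": dev, "threshold": 5.0, "passed": dev < 5.0,
    }
    from .geometry import LinkParams, check_watertight
    from .scenarios import build_variant_mesh

    mesh = build_variant_mesh("extramuscular", GeometryParams(), LinkParams())
    wt = check_watertight(mesh)
    results["watertight_default_mesh"] = {"value": float(wt), "threshold": 1.0, "passed": wt}
    return results
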