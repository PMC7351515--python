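"""Strain grids, myofascial load reports and force-balance summaries.

Fiber-direction Green-Lagrange strain is sampled on the fiber mesh at
the fascicle grid: two faces (lateral, medial) x fascicle sections
(nodal planes ordered proximal to distal along each fascicle) x fascicle
interfaces (across-fiber node columns).  Gauss-point strains are
extrapolated to element nodes with the standard trilinear extrapolation
and averaged over the elements adjacent to each node.

Myofascial loads are the local fiber-direction components of the forces
the extra-/intermuscular links exert on the muscle, normalized by the
single largest magnitude observed across the three cases of a model
variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fem import FemModel, SolutionState
from .geometry import MuscleMesh
from .scenarios import CaseResult

__all__ = [
    "StrainReport",
    "LoadReport",
    "fiber_strain_report",
    "myofascial_load_report",
    "proximo_distal_balance",
    "nodal_fiber_directions",
]

FACES = ("lateral", "medial")


def _extrapolation_matrix() -> np.ndarray:
    """(8 nodes x 8 Gauss points) trilinear extrapolation factors."""
    from .geometry import HEX_CORNERS

    s3 = np.sqrt(3.0)
    M = np.ones((8, 8))
    for d in range(3):
        M *= 0.5 * (1.0 + s3 * HEX_CORNERS[:, None, d] * HEX_CORNERS[None, :, d])
    return M

_EXTRAP = _extrapolation_matrix()


@dataclass
class StrainReport:
    """Fiber-direction strain grid (2 faces x sections x interfaces)."""

    grid: np.ndarray  # dimensionless Green-Lagrange strain
    converged_ratio: float

    @property
    def n_sections(self) -> int:
        return self.grid.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f, face in enumerate(FACES):
            for j in range(self.grid.shape[1]):
                for i in range(self.grid.shape[2]):
                    rows.append(
                        {
                            "face": face,
                            "section": _roman(j + 1),
                            "interface": i + 1,
                            "strain_pct": round(100.0 * self.grid[f, j, i], 1),
                        }
                    )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        rows = []
        for j in range(self.grid.shape[1]):
            sec = self.grid[:, j, :]
            rows.append(
                {
                    "section": _roman(j + 1),
                    "min": sec.min(),
                    "max": sec.max(),
                    "mean": sec.mean(),
                }
            )
        return pd.DataFrame(rows)


def _roman(n: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    return numerals[n - 1] if 1 <= n <= len(numerals) else str(n)


def nodal_fiber_strains(model: FemModel, u: np.ndarray) -> np.ndarray:
    """Per-node fiber strain of the fiber mesh (extrapolated + averaged)."""
    fam = model.families["myofiber"]
    st = fam.strain_state(u[fam.conn])
    eps_nodes = np.einsum("ag,eg->ea", _EXTRAP, st["eps22"])  # (ne, 8)
    acc = np.zeros(model.n_nodes)
    cnt = np.zeros(model.n_nodes)
    np.add.at(acc, fam.conn, eps_nodes)
    np.add.at(cnt, fam.conn, 1.0)
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1.0), 0.0)


def fiber_strain_report(result: CaseResult, mesh: MuscleMesh | None = None) -> StrainReport:
    """Sample fiber-direction strain on the fascicle grid of the target.

    Refuses unconverged solutions: the grid is only meaningful at
    equilibrium.  Zero strain marks the undeformed sarcomere state.
    """
    sol = result.solution
    if not sol.converged:
        raise ValueError(
            "solution did not converge "
            f"(residual ratio {sol.residual_ratio:.3e}); no strain report"
        )
    mesh = mesh or result.mesh
    nodal = nodal_fiber_strains(result.model, sol.displacement)
    grid = nodal[mesh.fascicle_grid]  # (2, n_sec, n_if)
    return StrainReport(grid=grid, converged_ratio=sol.residual_ratio)


def nodal_fiber_directions(mesh: MuscleMesh) -> np.ndarray:
    """Mean reference fiber axis per node (distally oriented, unit norm).

    Accumulated over both coincident meshes so matrix-mesh attachment
    nodes of the epimuscular links carry a direction too.
    """
    acc = np.zeros((mesh.n_nodes, 3))
    for conn, frames in (
        (mesh.myofiber_elements, mesh.myofiber_frames),
        (mesh.ecm_elements, mesh.ecm_frames),
    ):
        e2 = frames[:, :, 1]
        np.add.at(acc, conn.ravel(), np.repeat(e2, 8, axis=0))
    nrm = np.linalg.norm(acc, axis=1, keepdims=True)
    out = np.zeros_like(acc)
    ok = nrm[:, 0] > 1e-12
    out[ok] = acc[ok] / nrm[ok]
    return out


@dataclass
class LoadReport:
    """Per-link epimuscular myofascial loads for one case."""

    table: pd.DataFrame  # link id, kind, face, interface, node, axial, normalized, direction
    normalization: float

    @property
    def empty(self) -> bool:
        return self.table.empty


def _link_loads(result: CaseResult, target_only: bool = True) -> pd.DataFrame:
    """Fiber-direction force components of epimuscular links on the target."""
    mesh, model, sol = result.mesh, result.model, result.solution
    u = sol.displacement
    fdir = nodal_fiber_directions(mesh)
    spr = model.springs
    rows = []
    gforces = spr.ground_forces_on_nodes(u)
    for (ln, f) in zip(spr.grounds, gforces):
        if ln.kind != "extramuscular" or (target_only and ln.muscle != 0):
            continue
        axial = float(np.dot(f, fdir[ln.node_a]))
        rows.append(_load_row(ln, axial))
    pforces = spr.pair_forces_on_a(u)
    for (ln, f) in zip(spr.pairs, pforces):
        if ln.kind != "intermuscular":
            continue
        axial = float(np.dot(f, fdir[ln.node_a]))  # force on target node
        rows.append(_load_row(ln, axial))
    return pd.DataFrame(rows)


def _load_row(ln, axial: float) -> dict:
    return {
        "kind": ln.kind,
        "face": ln.face,
        "interface": ln.interface,
        "node": ln.node_a,
        "axial": axial,
        "direction": "proximal" if axial < 0 else "distal",
    }


def myofascial_load_report(results: dict[str, CaseResult]) -> dict[str, LoadReport]:
    """Load reports for cases I-III of one model-variant family.

    All three cases are normalized by the single largest fiber-direction
    load magnitude observed among them; for the isolated variant the
    reports are empty.
    """
    variants = {r.spec.model_variant for r in results.values()}
    if len(variants) != 1:
        raise ValueError("load report requires one model variant across cases")
    tables = {case: _link_loads(r) for case, r in results.items()}
    peak = max(
        (t["axial"].abs().max() for t in tables.values() if not t.empty),
        default=0.0,
    )
    out = {}
    for case, t in tables.items():
        if not t.empty:
            t = t.copy()
            t["normalized"] = t["axial"] / peak if peak > 0 else 0.0
        out[case] = LoadReport(table=t, normalization=peak)
    return out


@dataclass
class BalanceSummary:
    """Axial force bookkeeping at the tendon ends vs. myofascial loads."""

    proximal_reaction: float
    distal_reaction: float
    reaction_difference: float   # net epimuscular load inferred from ends
    net_link_axial: float        # summed axial link force on the muscle
    closure: float               # |difference - net link axial|
    max_reaction: float


def proximo_distal_balance(result: CaseResult) -> BalanceSummary:
    """Global axial equilibrium: the proximo-distal difference of end
    reactions equals the net axial myofascial load on the muscle."""
    mesh, model, sol = result.mesh, result.model, result.solution
    R = sol.reactions
    prox = float(R[mesh.node_sets["proximal_end"], 0].sum())
    dist = float(R[mesh.node_sets["distal_end"], 0].sum())
    spr = model.springs
    u = sol.displacement
    net = 0.0
    gforces = spr.ground_forces_on_nodes(u)
    for ln, f in zip(spr.grounds, gforces):
        if ln.kind == "extramuscular" and ln.muscle == 0:
            net += float(f[0])
    pforces = spr.pair_forces_on_a(u)
    for ln, f in zip(spr.pairs, pforces):
        if ln.kind == "intermuscular":
            net += float(f[0])
    diff = -(prox + dist)
    max_r = max(abs(prox), abs(dist), 1e-12)
    return BalanceSummary(
        proximal_reaction=prox,
        distal_reaction=dist,
        reaction_difference=diff,
        net_link_axial=net,
        closure=abs(diff - net),
        max_reaction=max_r,
    )
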