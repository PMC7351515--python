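"""Total-Lagrangian finite-element core.

8-node trilinear hexahedra with 2x2x2 Gauss quadrature, three material
families (ECM, myofiber, aponeurosis), uniaxial spring links, sparse
assembly and an incremental Newton-Raphson solver with a force-based
convergence criterion and automatic load-step bisection.

All element kernels are batched over the elements of a family with
numpy einsums; the element tangent is obtained by central finite
differences of the (energy-consistent) internal force, which eliminates
hand-derived consistent-tangent errors for the exotic material laws at a
cost that is irrelevant at these mesh sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import materials as mat
from .geometry import HEX_CORNERS, MuscleMesh

__all__ = [
    "GAUSS_POINTS",
    "GAUSS_WEIGHTS",
    "shape_functions",
    "shape_gradients",
    "green_lagrange",
    "SolverParams",
    "BoundaryConditions",
    "Phase",
    "SolutionState",
    "SolverError",
    "FemModel",
    "spring_force",
    "assemble",
    "newton_solve",
]

GAUSS_POINTS = HEX_CORNERS / np.sqrt(3.0)
GAUSS_WEIGHTS = np.ones(8)


def shape_functions(points) -> np.ndarray:
    """Trilinear shape functions N_a at local points (m, 3) -> (m, 8)."""
    p = np.atleast_2d(points)
    return (
        (1.0 + p[:, None, 0] * HEX_CORNERS[None, :, 0])
        * (1.0 + p[:, None, 1] * HEX_CORNERS[None, :, 1])
        * (1.0 + p[:, None, 2] * HEX_CORNERS[None, :, 2])
        / 8.0
    )


def shape_gradients(points) -> np.ndarray:
    """dN_a/dxi at local points (m, 3) -> (m, 8, 3)."""
    p = np.atleast_2d(points)
    m = p.shape[0]
    out = np.empty((m, 8, 3))
    for d in range(3):
        terms = [
            (1.0 + p[:, None, e] * HEX_CORNERS[None, :, e]) for e in range(3) if e != d
        ]
        out[:, :, d] = HEX_CORNERS[None, :, d] / 8.0 * terms[0] * terms[1]
    return out

_DN = shape_gradients(GAUSS_POINTS)  # (8 gp, 8 nodes, 3)


def green_lagrange(F) -> np.ndarray:
    """Green-Lagrange strain E = (F^T F - I)/2 for (..., 3, 3) F."""
    F = np.asarray(F, dtype=float)
    C = np.swapaxes(F, -1, -2) @ F
    return 0.5 * (C - np.eye(3))


class SolverError(RuntimeError):
    """Newton solver failure (after load-step bisection)."""


@dataclass
class SolverParams:
    """Newton/load-stepping controls.

    ``tolerance`` is the force-based convergence ratio (residual norm
    over reference internal-force norm, floored by ``unit_floor``); after
    meeting it, iterations continue toward ``polish_rtol`` while progress
    lasts, so converged states are effectively exact equilibria.
    """

    tolerance: float = 0.005
    unit_floor: float = 1.0
    polish_rtol: float = 1e-10
    max_iterations: int = 30
    displacement_steps: int = 4
    activation_steps: int = 10
    max_bisections: int = 4
    fd_step: float = 1e-6
    norm: str = "l2"  # or "linf"

    def validate(self) -> list[str]:
        problems = []
        if not self.tolerance > 0:
            problems.append("solver.tolerance must be > 0")
        if self.displacement_steps < 1 or self.activation_steps < 1:
            problems.append("solver step counts must be >= 1")
        if self.norm not in ("l2", "linf"):
            problems.append("solver.norm must be 'l2' or 'linf'")
        return problems


@dataclass
class BoundaryConditions:
    """Prescribed nodal displacements; free DOFs are the complement."""

    mask: np.ndarray  # (n_nodes, 3) bool
    values: np.ndarray  # (n_nodes, 3) float, read where mask is True

    @classmethod
    def empty(cls, n_nodes: int) -> "BoundaryConditions":
        return cls(np.zeros((n_nodes, 3), bool), np.zeros((n_nodes, 3)))

    def prescribe(self, node_ids, axis=None, value=0.0):
        axes = range(3) if axis is None else [axis]
        for ax in axes:
            self.mask[node_ids, ax] = True
            self.values[node_ids, ax] = value


@dataclass
class Phase:
    """One loading phase: prescribed values and activation are ramped
    linearly from their start to end values over ``n_steps`` steps."""

    values_start: np.ndarray
    values_end: np.ndarray
    b3_start: float
    b3_end: float
    n_steps: int
    label: str = ""


@dataclass
class SolutionState:
    """Converged solution: displacements, activation, diagnostics."""

    displacement: np.ndarray
    activation: float
    converged: bool
    residual_ratio: float
    reactions: np.ndarray
    history: list = field(default_factory=list)


# --------------------------------------------------------------------------
# Element family kernels
# --------------------------------------------------------------------------

class _Family:
    """Batched kernel for one element family (shared quadrature data)."""

    def __init__(self, name: str, conn: np.ndarray, nodes: np.ndarray,
                 frames: np.ndarray | None, params: mat.MaterialParams,
                 activation_mask: np.ndarray | None = None):
        self.name = name
        self.conn = np.asarray(conn, dtype=int)
        self.ne = self.conn.shape[0]
        self.params = params
        self.frames = frames
        X = nodes[self.conn]  # (ne, 8, 3)
        J = np.einsum("eak,gad->egkd", X, _DN)  # (ne, 8gp, 3, 3)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise ValueError(f"non-positive Jacobian in family {name}")
        Jinv = np.linalg.inv(J)
        self.dNdX = np.einsum("gad,egdk->egak", _DN, Jinv)  # (ne, 8gp, 8, 3)
        self.dV = detJ * GAUSS_WEIGHTS[None, :]
        self.Ve = self.dV.sum(axis=1)
        if activation_mask is None and name == "myofiber":
            activation_mask = np.ones(self.ne)
        self.activation_mask = activation_mask
        if frames is not None:
            self.r2 = frames[:, :, 1]  # fiber axis per element

    # -- kinematics -------------------------------------------------------
    def deformation(self, u_e: np.ndarray):
        """F at every Gauss point; ``u_e`` may carry leading batch axes."""
        F = np.eye(3) + np.einsum("...eai,egaj->...egij", u_e, self.dNdX)
        return F

    def strain_state(self, u_e: np.ndarray) -> dict:
        F = self.deformation(u_e)
        C = np.einsum("...egki,...egkj->...egij", F, F)
        E = 0.5 * (C - np.eye(3))
        out = {"F": F, "C": C, "E": E, "I3": np.linalg.det(C)}
        if self.frames is not None:
            R = self.frames
            out["E_local"] = np.einsum("eki,...egkl,elj->...egij", R, E, R)
            out["eps22"] = np.einsum("ek,...egkl,el->...eg", self.r2, E, self.r2)
        return out

    # -- constitutive -----------------------------------------------------
    def _pk2(self, st: dict, b3: float) -> np.ndarray:
        p = self.params
        if self.name == "ecm":
            S_full = mat.ecm_anisotropic_stress(st["E_local"], p.ecm)
            # halve off-diagonals: work-conjugate form for full contraction
            S_work = 0.5 * (S_full + np.eye(3) * S_full)
            R = self.frames
            S = np.einsum("eik,...egkl,ejl->...egij", R, S_work, R)
            I3 = st["I3"]
            if np.any(I3 <= 0):
                raise ValueError("element inversion in ECM family")
            I3avg = np.einsum("eg,...eg->...e", self.dV, I3) / self.Ve
            coef = 4.0 * (
                p.ecm.Ss * (I3 - 1.0) + p.ecm.Sf * (I3avg[..., None] - 1.0)
            )
            Cinv = np.linalg.inv(st["C"])
            S = S + (coef * I3)[..., None, None] * Cinv
            return S
        if self.name == "myofiber":
            b3e = (b3 * self.activation_mask)[:, None]
            S22 = mat.fiber_pk2_stress(st["eps22"], b3e, p.fiber)
            r2r2 = np.einsum("ei,ej->eij", self.r2, self.r2)[:, None]
            return S22[..., None, None] * r2r2
        # aponeurosis
        return mat.aponeurosis_pk2(st["F"], p.aponeurosis)

    # -- integrals --------------------------------------------------------
    def force(self, u_e: np.ndarray, b3: float = 0.0) -> np.ndarray:
        """Internal nodal forces (..., ne, 8, 3): element energy gradient."""
        st = self.strain_state(u_e)
        S = self._pk2(st, b3)
        P = np.einsum("...egik,...egkj->...egij", st["F"], S)
        return np.einsum("...egij,egaj,eg->...eai", P, self.dNdX, self.dV)

    def energy(self, u_e: np.ndarray, b3: float = 0.0) -> np.ndarray:
        """Total strain energy per element (..., ne)."""
        st = self.strain_state(u_e)
        p = self.params
        if self.name == "ecm":
            W = mat.ecm_anisotropic_energy(st["E_local"], p.ecm)
            I3 = st["I3"]
            I3avg = np.einsum("eg,...eg->...e", self.dV, I3) / self.Ve
            W = (
                W
                + p.ecm.Ss * (I3 - 1.0) ** 2
                + p.ecm.Sf * (I3avg[..., None] - 1.0) ** 2
            )
        elif self.name == "myofiber":
            b3e = (b3 * self.activation_mask)[:, None]
            W = mat.fiber_energy_density(st["eps22"], b3e, p.fiber)
        else:
            W = mat.aponeurosis_energy(st["F"], p.aponeurosis)
        return np.einsum("...eg,eg->...e", W, self.dV)

    def tangent(self, u_e: np.ndarray, b3: float, h: float) -> np.ndarray:
        """Element stiffness (ne, 24, 24) by central FD of the force.

        All 48 perturbed states are evaluated in a single batched call.
        """
        U = np.broadcast_to(u_e, (48,) + u_e.shape).copy()
        U = U.reshape(48, self.ne, 24)
        idx = np.arange(24)
        U[idx, :, idx] += h
        U[idx + 24, :, idx] -= h
        f = self.force(U.reshape(48, self.ne, 8, 3), b3).reshape(48, self.ne, 24)
        K = np.transpose((f[:24] - f[24:]) / (2.0 * h), (1, 2, 0))
        return 0.5 * (K + np.swapaxes(K, 1, 2))


# --------------------------------------------------------------------------
# Springs
# --------------------------------------------------------------------------

def spring_force(link, nodes: np.ndarray, u: np.ndarray):
    """Force the link exerts on its end nodes.

    Returns ``(f_a, f_b)``; for grounded links ``f_b`` is the force on
    the anchor.  Magnitude ``k*(l - l0)`` along the current chord;
    zero-reference-length links act on the end-to-end displacement
    vector directly.
    """
    pa = nodes[link.node_a] + u[link.node_a]
    if link.node_b >= 0:
        pb = nodes[link.node_b] + u[link.node_b]
    else:
        pb = np.asarray(link.anchor, dtype=float)
    d = pb - pa
    if link.ref_length == 0.0:
        f_a = link.stiffness * d
    else:
        l = np.linalg.norm(d)
        if l < 1e-14:
            return np.zeros(3), np.zeros(3)
        f_a = link.stiffness * (l - link.ref_length) * d / l
    return f_a, -f_a


class _Springs:
    """Vectorized spring assembly (pairs and grounded links)."""

    def __init__(self, links, nodes: np.ndarray):
        pairs = [ln for ln in links if ln.node_b >= 0]
        grounds = [ln for ln in links if ln.node_b < 0]
        self.pa = np.array([ln.node_a for ln in pairs], int)
        self.pb = np.array([ln.node_b for ln in pairs], int)
        self.pk = np.array([ln.stiffness for ln in pairs])
        self.pl0 = np.array([ln.ref_length for ln in pairs])
        self.pd0 = (
            nodes[self.pb] - nodes[self.pa] if pairs else np.zeros((0, 3))
        )
        self.gn = np.array([ln.node_a for ln in grounds], int)
        self.gk = np.array([ln.stiffness for ln in grounds])
        self.gl0 = np.array([ln.ref_length for ln in grounds])
        self.gd0 = (
            np.array([ln.anchor for ln in grounds]) - nodes[self.gn]
            if grounds
            else np.zeros((0, 3))
        )
        self.pairs, self.grounds = pairs, grounds

    def _pair_dirs(self, u):
        d = self.pd0 + u[self.pb] - u[self.pa]
        l = np.linalg.norm(d, axis=1)
        return d, l

    def _ground_dirs(self, u):
        d = self.gd0 - u[self.gn]
        l = np.linalg.norm(d, axis=1)
        return d, l

    @staticmethod
    def _axial(d, l, l0, k):
        """Energy-gradient magnitude vector k*(l-l0)*dhat, robust at l=0."""
        safe = np.maximum(l, 1e-14)
        coef = np.where(l0 == 0.0, k, k * (l - l0) / safe)
        return coef[:, None] * d

    def add_residual(self, u, R):
        if len(self.pa):
            d, l = self._pair_dirs(u)
            f = self._axial(d, l, self.pl0, self.pk)
            np.add.at(R, self.pa, -f)
            np.add.at(R, self.pb, f)
        if len(self.gn):
            d, l = self._ground_dirs(u)
            f = self._axial(d, l, self.gl0, self.gk)
            np.add.at(R, self.gn, -f)

    def ground_forces_on_nodes(self, u):
        """(n_ground, 3) force each grounded link exerts on its node."""
        if not len(self.gn):
            return np.zeros((0, 3))
        d, l = self._ground_dirs(u)
        return self._axial(d, l, self.gl0, self.gk)

    def pair_forces_on_a(self, u):
        if not len(self.pa):
            return np.zeros((0, 3))
        d, l = self._pair_dirs(u)
        return self._axial(d, l, self.pl0, self.pk)

    @staticmethod
    def _block(d, l, l0, k):
        """3x3 Hessian block H = d^2E/du^2 per link (m, 3, 3)."""
        m = len(k)
        eye = np.broadcast_to(np.eye(3), (m, 3, 3))
        safe = np.maximum(l, 1e-14)
        dhat = d / safe[:, None]
        ddt = np.einsum("mi,mj->mij", dhat, dhat)
        gen = k[:, None, None] * (ddt + ((l - l0) / safe)[:, None, None] * (eye - ddt))
        lin = k[:, None, None] * eye
        use_lin = (l0 == 0.0) | (l < 1e-12)
        return np.where(use_lin[:, None, None], lin, gen)

    def triplets(self, u):
        rows, cols, vals = [], [], []
        ax = np.arange(3)
        if len(self.pa):
            d, l = self._pair_dirs(u)
            H = self._block(d, l, self.pl0, self.pk)
            da = (3 * self.pa[:, None] + ax).astype(np.int64)
            db = (3 * self.pb[:, None] + ax).astype(np.int64)
            for dofs1, dofs2, sgn in ((da, da, 1.0), (db, db, 1.0), (da, db, -1.0), (db, da, -1.0)):
                r = np.repeat(dofs1, 3, axis=1).ravel()
                c = np.tile(dofs2, (1, 3)).ravel()
                rows.append(r); cols.append(c); vals.append(sgn * H.reshape(len(l), 9).ravel())
        if len(self.gn):
            d, l = self._ground_dirs(u)
            H = self._block(d, l, self.gl0, self.gk)
            dg = (3 * self.gn[:, None] + ax).astype(np.int64)
            r = np.repeat(dg, 3, axis=1).ravel()
            c = np.tile(dg, (1, 3)).ravel()
            rows.append(r); cols.append(c); vals.append(H.reshape(len(l), 9).ravel())
        if not rows:
            return np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0)
        return np.concatenate(rows), np.concatenate(cols), np.concatenate(vals)


# --------------------------------------------------------------------------
# Model
# --------------------------------------------------------------------------

class FemModel:
    """Assembled muscle model: element families + springs over one mesh."""

    def __init__(self, mesh: MuscleMesh, params: mat.MaterialParams,
                 activation_mask: np.ndarray | None = None):
        self.mesh = mesh
        self.params = params
        if activation_mask is None:
            activation_mask = np.ones(len(mesh.myofiber_elements))
        self.families = {
            "ecm": _Family("ecm", mesh.ecm_elements, mesh.nodes, mesh.ecm_frames, params),
            "myofiber": _Family(
                "myofiber", mesh.myofiber_elements, mesh.nodes, mesh.myofiber_frames,
                params, activation_mask,
            ),
        }
        if len(mesh.apo_elements):
            self.families["aponeurosis"] = _Family(
                "aponeurosis", mesh.apo_elements, mesh.nodes, None, params
            )
        self.springs = _Springs(mesh.links, mesh.nodes)
        self.n_nodes = mesh.n_nodes
        self.ndof = 3 * self.n_nodes
        self._edofs = {
            name: (3 * fam.conn[:, :, None] + np.arange(3)).reshape(fam.ne, 24)
            for name, fam in self.families.items()
        }

    # -- global quantities ------------------------------------------------
    def residual(self, u: np.ndarray, b3: float = 0.0):
        """Internal force vector (n_nodes, 3) = gradient of total energy."""
        R = np.zeros((self.n_nodes, 3))
        for fam in self.families.values():
            f = fam.force(u[fam.conn], b3)
            np.add.at(R, fam.conn, f)
        self.springs.add_residual(u, R)
        return R

    def total_energy(self, u: np.ndarray, b3: float = 0.0) -> float:
        E = 0.0
        for fam in self.families.values():
            E += fam.energy(u[fam.conn], b3).sum()
        spr = self.springs
        if len(spr.pa):
            d, l = spr._pair_dirs(u)
            E += float(np.sum(0.5 * spr.pk * (l - spr.pl0) ** 2))
        if len(spr.gn):
            d, l = spr._ground_dirs(u)
            E += float(np.sum(0.5 * spr.gk * (l - spr.gl0) ** 2))
        return float(E)

    def tangent(self, u: np.ndarray, b3: float = 0.0, fd_step: float = 1e-6) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for name, fam in self.families.items():
            Ke = fam.tangent(u[fam.conn], b3, fd_step)
            ed = self._edofs[name]
            rows.append(np.repeat(ed, 24, axis=1).ravel())
            cols.append(np.tile(ed, (1, 24)).ravel())
            vals.append(Ke.ravel())
        r, c, v = self.springs.triplets(u)
        rows.append(r); cols.append(c); vals.append(v)
        K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ndof, self.ndof),
        ).tocsr()
        return K

    def strain_state(self, family: str, u: np.ndarray) -> dict:
        fam = self.families[family]
        return fam.strain_state(u[fam.conn])


def assemble(model: FemModel, u: np.ndarray, b3: float = 0.0):
    """Global residual vector and sparse tangent at state (u, b3)."""
    return model.residual(u, b3).ravel(), model.tangent(u, b3)


# --------------------------------------------------------------------------
# Newton solver
# --------------------------------------------------------------------------

def _diagnose_singular(K_ff: sp.csr_matrix, free_dofs: np.ndarray) -> str:
    try:
        dense = K_ff.toarray()
        w, v = np.linalg.eigh(0.5 * (dense + dense.T))
        null = np.flatnonzero(np.abs(w) < 1e-8 * max(np.abs(w).max(), 1.0))
        dofs = set()
        for m in null[:6]:
            amp = np.abs(v[:, m])
            dofs.update(free_dofs[np.argsort(amp)[-6:]].tolist())
        if dofs:
            names = [f"node {d // 3} axis {'xyz'[d % 3]}" for d in sorted(dofs)]
            return "unconstrained DOFs (rigid-body modes?): " + ", ".join(names)
    except Exception:
        pass
    return "singular tangent (unconstrained rigid-body modes?)"


def newton_solve(
    model: FemModel,
    bc: BoundaryConditions,
    phases: list[Phase],
    sp_params: SolverParams | None = None,
    u0: np.ndarray | None = None,
    log: list | None = None,
) -> SolutionState:
    """Incrementally apply the loading phases and iterate to equilibrium.

    Within each load step Newton iterations run until the force residual
    on the free DOFs drops below ``tolerance`` times the reference
    internal-force norm (floored at ``unit_floor``); iterations then
    continue toward ``polish_rtol`` while they keep making progress.
    Non-convergent steps are bisected up to ``max_bisections`` deep.
    """
    spp = sp_params or SolverParams()
    u = np.zeros((model.n_nodes, 3)) if u0 is None else u0.copy()
    maskf = bc.mask.ravel()
    free = np.flatnonzero(~maskf)
    history: list = []

    def norm(vec):
        return float(np.linalg.norm(vec)) if spp.norm == "l2" else float(
            np.max(np.abs(vec), initial=0.0)
        )

    def newton(u, presc, b3):
        # trial iterates far from equilibrium may overflow the exponential
        # material laws; non-finite residuals are handled by backtracking
        u = u.copy()
        u.reshape(-1)[maskf] = presc.ravel()[maskf]
        prev_rr = np.inf
        rr = np.inf
        try:
            R = model.residual(u, b3)
        except ValueError:
            return u, np.inf, False  # inverted element at step application
        for it in range(spp.max_iterations):
            Rf = R.ravel()[free]
            ref = max(norm(R.ravel()), spp.unit_floor)
            rr = norm(Rf) / ref
            history.append({"b3": b3, "iter": it, "ratio": rr})
            if log is not None:
                log.append((b3, it, rr))
            if rr <= spp.polish_rtol:
                break
            if rr <= spp.tolerance and rr > prev_rr / 1.5:
                break  # converged; progress has stalled near machine floor
            if it > 0 and rr > 100.0 * prev_rr:
                return u, rr, False
            try:
                K = model.tangent(u, b3, spp.fd_step)
            except ValueError:
                return u, rr, False
            K_ff = K[free][:, free].tocsc()
            try:
                du = spla.splu(K_ff).solve(-R.ravel()[free])
            except RuntimeError:
                raise SolverError(_diagnose_singular(K_ff, free))
            if not np.all(np.isfinite(du)):
                return u, rr, False
            # backtrack if the full update inverts an element
            accepted = False
            for alpha in (1.0, 0.5, 0.25, 0.125, 0.0625):
                u_try = u.copy()
                u_try.reshape(-1)[free] += alpha * du
                try:
                    R_try = model.residual(u_try, b3)
                except ValueError:
                    continue
                if np.all(np.isfinite(R_try)):
                    u, R, accepted = u_try, R_try, True
                    break
            if not accepted:
                return u, rr, False
            prev_rr = rr
        return u, rr, rr <= spp.tolerance

    b3 = phases[0].b3_start if phases else 0.0
    rr_final = 0.0
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for phase in phases:
            pending = [
                ((i / phase.n_steps), ((i + 1) / phase.n_steps), 0)
                for i in range(phase.n_steps)
            ]
            while pending:
                t0, t1, depth = pending.pop(0)
                presc = phase.values_start + t1 * (phase.values_end - phase.values_start)
                b3_t = phase.b3_start + t1 * (phase.b3_end - phase.b3_start)
                u_saved = u.copy()
                u_new, rr, ok = newton(u, presc, b3_t)
                if ok:
                    u, b3, rr_final = u_new, b3_t, rr
                else:
                    if depth >= spp.max_bisections:
                        raise SolverError(
                            f"no convergence in phase {phase.label!r} at t={t1:.3f} "
                            f"(residual ratio {rr:.3e})"
                        )
                    mid = 0.5 * (t0 + t1)
                    pending = [(t0, mid, depth + 1), (mid, t1, depth + 1)] + pending
                    u = u_saved

    R = model.residual(u, b3)
    return SolutionState(
        displacement=u,
        activation=b3,
        converged=True,
        residual_ratio=rr_final,
        reactions=R,
        history=history,
    )
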