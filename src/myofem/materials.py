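"""Constitutive laws for the linked fiber-matrix muscle model.

Three element families carry three material descriptions:

* **ECM element** — a nonlinear, anisotropic strain-energy density in the
  local (cross-fiber, fiber, thickness) frame plus a two-part volume
  penalty (pointwise "solid" term and element-mean "fluid" term) that
  together enforce near-incompressibility of muscle tissue.
* **Myofiber element** — a uniaxial Cauchy stress acting along the local
  fiber direction only: an active contractile part (piecewise
  exponential, peak of 1.0 at zero fiber strain) plus an intracellular
  passive (titin) parabola that engages in lengthening only.
* **Aponeurosis element** — a two-parameter Mooney-Rivlin hyperelastic
  law on the reduced invariants of the right Cauchy-Green tensor.

Stresses are second Piola-Kirchhoff (PK2), work-conjugate to the
Green-Lagrange strain; every stress routine is the analytic derivative of
the corresponding energy, which the test suite verifies against central
finite differences.

Component convention: symmetric local strain tensors are read through
their six independent components {11, 22, 33, 12, 23, 31}.  Off-diagonal
*stress* entries returned here are derivatives with respect to the single
independent shear component; the finite-element kernels halve them when
forming the tensor that is double-contracted with the full strain
variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EcmParams",
    "FiberParams",
    "AponeurosisParams",
    "MaterialParams",
    "LocalStrainState",
    "ecm_anisotropic_energy",
    "ecm_anisotropic_stress",
    "volume_penalty_energy",
    "active_stress",
    "titin_stress",
    "fiber_total_stress",
    "fiber_pk2_stress",
    "fiber_energy_density",
    "aponeurosis_energy",
    "aponeurosis_pk2",
]


# --------------------------------------------------------------------------
# Parameter blocks
# --------------------------------------------------------------------------

@dataclass
class EcmParams:
    """Extracellular-matrix constants (normalized stress units).

    ``k`` is the initial passive stiffness; ``a11..a31`` are the
    exponential stiffness exponents per local direction pair (1 =
    cross-fiber, 2 = fiber, 3 = thickness); ``Ss``/``Sf`` weight the
    solid (pointwise) and fluid (element-mean) volume penalties.
    """

    k: float = 0.05
    a11: float = 8.0
    a22: float = 6.0
    a33: float = 8.0
    a12: float = 6.0
    a23: float = 6.0
    a31: float = 6.0
    Ss: float = 5.0
    Sf: float = 20.0

    def validate(self) -> list[str]:
        problems = []
        for name in ("k", "a11", "a22", "a33", "a12", "a23", "a31", "Ss", "Sf"):
            if not getattr(self, name) > 0:
                problems.append(f"materials.ecm.{name} must be > 0")
        return problems

    def exponent_matrix(self) -> np.ndarray:
        """3x3 matrix of a_ij exponents in the local frame."""
        return np.array(
            [
                [self.a11, self.a12, self.a31],
                [self.a12, self.a22, self.a23],
                [self.a31, self.a23, self.a33],
            ]
        )


@dataclass
class FiberParams:
    """Myofiber constants.

    ``b1``/``b2`` shape the active stress-strain curve (shortening /
    lengthening branches); ``b3`` is the activation level (0 passive,
    1 maximal).  ``t1..t3`` are the titin parabola coefficients.
    ``clamp_titin_nonnegative`` clamps the titin parabola at zero (on by
    default: the fitted parabola is slightly negative near zero strain,
    and without the clamp that offset would pre-stress the reference
    state, which by definition is the undeformed, stress-free sarcomere
    configuration; disable it to evaluate the fit as printed).
    ``stress_measure`` selects how the uniaxial Cauchy fiber stress enters
    the total-Lagrangian formulation: ``"cauchy_pullback"`` divides by the
    squared fiber stretch (pull-back at unit volume ratio), while
    ``"pk2_direct"`` uses it unchanged as a local PK2 component.
    """

    b1: float = 30.0
    b2: float = -6.0
    b3: float = 1.0
    t1: float = 0.522
    t2: float = 0.019
    t3: float = -0.002
    clamp_titin_nonnegative: bool = True
    stress_measure: str = "cauchy_pullback"

    def validate(self) -> list[str]:
        problems = []
        if not 0.0 <= self.b3 <= 1.0:
            problems.append("materials.fiber.b3 must be in [0, 1]")
        if self.stress_measure not in ("cauchy_pullback", "pk2_direct"):
            problems.append(
                "materials.fiber.stress_measure must be "
                "'cauchy_pullback' or 'pk2_direct'"
            )
        return problems


@dataclass
class AponeurosisParams:
    """Two-parameter Mooney-Rivlin constants for the aponeurosis sheets.

    The bulk modulus is always derived as ``2(a10+a01)/(1-2*poisson)``;
    it is a property, never set independently.
    """

    a10: float = 14.4
    a01: float = 3.6
    poisson: float = 0.3

    @property
    def bulk(self) -> float:
        return 2.0 * (self.a10 + self.a01) / (1.0 - 2.0 * self.poisson)

    @property
    def youngs_small_strain(self) -> float:
        """Small-strain Young modulus 2*mu*(1+nu) with mu = 2(a10+a01)."""
        return 4.0 * (self.a10 + self.a01) * (1.0 + self.poisson)

    def validate(self) -> list[str]:
        problems = []
        if not 0.0 <= self.poisson < 0.5:
            problems.append("materials.aponeurosis.poisson must be in [0, 0.5)")
        if self.a10 + self.a01 <= 0:
            problems.append("materials.aponeurosis.a10 + a01 must be > 0")
        return problems


@dataclass
class MaterialParams:
    """Bundle of all constitutive constants used by one model run."""

    ecm: EcmParams = field(default_factory=EcmParams)
    fiber: FiberParams = field(default_factory=FiberParams)
    aponeurosis: AponeurosisParams = field(default_factory=AponeurosisParams)

    def validate(self) -> list[str]:
        return self.ecm.validate() + self.fiber.validate() + self.aponeurosis.validate()


@dataclass
class LocalStrainState:
    """Strain state at a Gauss point, expressed in the local frame.

    ``E_local`` is the symmetric Green-Lagrange tensor with axes
    (1 = cross-fiber, 2 = fiber, 3 = thickness); ``I3`` is the
    determinant of the right Cauchy-Green tensor (squared volume ratio
    convention is *not* used here: I3 itself is treated as the local
    volume ratio, matching the penalty the constants were tuned for);
    ``I3avg`` is the element's weighted mean of I3.
    """

    E_local: np.ndarray
    I3: float = 1.0
    I3avg: float = 1.0


# --------------------------------------------------------------------------
# ECM element
# --------------------------------------------------------------------------

def _as_E(E_local) -> np.ndarray:
    if isinstance(E_local, LocalStrainState):
        return np.asarray(E_local.E_local, dtype=float)
    return np.asarray(E_local, dtype=float)


def _component_view(E: np.ndarray):
    """Split (..., 3, 3) strain into normal and shear independent parts."""
    normals = np.stack([E[..., 0, 0], E[..., 1, 1], E[..., 2, 2]], axis=-1)
    shears = np.stack([E[..., 0, 1], E[..., 1, 2], E[..., 2, 0]], axis=-1)
    return normals, shears


def ecm_anisotropic_energy(E_local, p: EcmParams):
    """Anisotropic ECM strain-energy density.

    Sum over the six independent strain components of
    ``k * (exp(a*eps) - a*eps)`` — exponential (asymmetric) in the
    normal directions; even in the shear components, so the shear stress
    derived from it is an odd function of the shear strain.
    """
    E = _as_E(E_local)
    normals, shears = _component_view(E)
    a_n = np.array([p.a11, p.a22, p.a33])
    a_s = np.array([p.a12, p.a23, p.a31])
    w_n = p.k * (np.exp(a_n * normals) - a_n * normals)
    abs_s = np.abs(shears)
    w_s = p.k * (np.exp(a_s * abs_s) - a_s * abs_s)
    return np.sum(w_n, axis=-1) + np.sum(w_s, axis=-1)


def ecm_anisotropic_stress(E_local, p: EcmParams):
    """Local PK2 stress of the anisotropic ECM part.

    Component (i, j) is the derivative of the energy with respect to the
    independent strain component eps_ij: normal components
    ``k*a*(exp(a*eps) - 1)``; shear components odd,
    ``sign(eps)*k*a*(exp(a*|eps|) - 1)``.
    """
    E = _as_E(E_local)
    normals, shears = _component_view(E)
    a_n = np.array([p.a11, p.a22, p.a33])
    a_s = np.array([p.a12, p.a23, p.a31])
    s_n = p.k * a_n * (np.exp(a_n * normals) - 1.0)
    s_s = np.sign(shears) * p.k * a_s * (np.exp(a_s * np.abs(shears)) - 1.0)
    S = np.zeros_like(E)
    S[..., 0, 0] = s_n[..., 0]
    S[..., 1, 1] = s_n[..., 1]
    S[..., 2, 2] = s_n[..., 2]
    S[..., 0, 1] = S[..., 1, 0] = s_s[..., 0]
    S[..., 1, 2] = S[..., 2, 1] = s_s[..., 1]
    S[..., 2, 0] = S[..., 0, 2] = s_s[..., 2]
    return S


def volume_penalty_energy(I3_points, weights, p: EcmParams) -> np.ndarray:
    """Per-Gauss-point volume-penalty energy densities for one element.

    ``Ss*(I3-1)^2`` penalizes pointwise (solid) volume change and
    ``Sf*(I3avg-1)^2`` penalizes the weighted element mean (fluid
    redistribution is free, net fluid volume change is not).
    """
    I3 = np.asarray(I3_points, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(I3 <= 0):
        raise ValueError("element inversion: nonpositive local volume ratio I3")
    w = w / w.sum()
    I3avg = float(np.dot(w, I3))
    return p.Ss * (I3 - 1.0) ** 2 + p.Sf * (I3avg - 1.0) ** 2


# --------------------------------------------------------------------------
# Myofiber element
# --------------------------------------------------------------------------

def active_stress(eps22, b3):
    """Active contractile Cauchy stress along the fiber direction.

    Piecewise exponential in the fiber Green-Lagrange strain, continuous
    at zero where it attains its maximum ``b3`` (unity at full
    activation): ``b3*exp(b2*eps^2)`` on the lengthening branch and
    ``b3*exp(b1*eps^3)`` on the shortening branch.
    """
    return _active_stress_p(eps22, b3, FiberParams())


def _active_stress_p(eps22, b3, p: FiberParams):
    eps = np.asarray(eps22, dtype=float)
    out = np.where(
        eps > 0.0,
        np.exp(p.b2 * eps**2),
        np.exp(p.b1 * eps**3),
    )
    return b3 * out


def titin_stress(eps22, p: FiberParams | None = None):
    """Intracellular passive (titin) Cauchy stress: a parabola for
    lengthening, exactly zero for shortening."""
    if p is None:
        p = FiberParams()
    eps = np.asarray(eps22, dtype=float)
    val = p.t1 * eps**2 + p.t2 * eps + p.t3
    if p.clamp_titin_nonnegative:
        val = np.maximum(val, 0.0)
    return np.where(eps < 0.0, 0.0, val)


def fiber_total_stress(eps22, b3, p: FiberParams | None = None):
    """Total fiber-direction Cauchy stress: active + titin.

    Acts in the local fiber direction exclusively; all other local
    stress components of the myofiber element are zero.
    """
    if p is None:
        p = FiberParams()
    return _active_stress_p(eps22, b3, p) + titin_stress(eps22, p)


def fiber_pk2_stress(eps22, b3, p: FiberParams | None = None):
    """Fiber stress as a local PK2 component for assembly.

    With the default ``cauchy_pullback`` measure the Cauchy value is
    divided by the squared fiber stretch ``2*eps22 + 1`` (pull-back at
    unit volume ratio — the ECM penalty keeps the tissue
    near-incompressible); ``pk2_direct`` uses the Cauchy value unchanged.
    """
    if p is None:
        p = FiberParams()
    eps = np.asarray(eps22, dtype=float)
    sigma = fiber_total_stress(eps, b3, p)
    if p.stress_measure == "pk2_direct":
        return sigma
    lam2 = 2.0 * eps + 1.0
    if np.any(lam2 <= 1e-6):
        raise ValueError("fiber stretch collapsed (eps22 <= -0.5)")
    return sigma / lam2


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)


def _titin_clamp_root(p: FiberParams) -> float | None:
    """Strain where the clamped titin parabola starts to engage."""
    if not p.clamp_titin_nonnegative or p.t1 <= 0:
        return None
    disc = p.t2**2 - 4.0 * p.t1 * p.t3
    if disc <= 0:
        return None
    r = (-p.t2 + np.sqrt(disc)) / (2.0 * p.t1)
    return float(r) if r > 0 else None


def fiber_energy_density(eps22, b3, p: FiberParams | None = None):
    """Primitive of the fiber PK2 stress from zero strain.

    Computed with fixed 24-point Gauss-Legendre quadrature, split at the
    titin clamp root where the integrand has a derivative kink, so the
    result is machine-accurate and the assembled fiber force is the
    gradient of this energy to quadrature precision.
    """
    if p is None:
        p = FiberParams()
    eps = np.asarray(eps22, dtype=float)
    b3a = np.broadcast_to(
        np.asarray(b3, dtype=float),
        np.broadcast_shapes(np.shape(b3), eps.shape),
    )

    def segment(a, b):
        mid = 0.5 * (a + b)
        half = 0.5 * (b - a)
        s = mid[..., None] + half[..., None] * _GL_NODES
        vals = fiber_pk2_stress(s, b3a[..., None], p)
        return half * np.sum(vals * _GL_WEIGHTS, axis=-1)

    zero = np.zeros_like(eps)
    root = _titin_clamp_root(p)
    if root is None:
        return segment(zero, eps)
    c = np.minimum(eps, root)
    return segment(zero, c) + segment(c, eps)


# --------------------------------------------------------------------------
# Aponeurosis element
# --------------------------------------------------------------------------

def _mr_invariants(C: np.ndarray):
    I1 = np.trace(C, axis1=-2, axis2=-1)
    C2 = C @ C
    I2 = 0.5 * (I1**2 - np.trace(C2, axis1=-2, axis2=-1))
    I3 = np.linalg.det(C)
    return I1, I2, I3


def aponeurosis_energy(F, p: AponeurosisParams):
    """Mooney-Rivlin energy density on reduced invariants.

    ``W = a10*(Ibar1 - 3) + a01*(Ibar2 - 3) + kappa/2*(Ibar3 - 1)^2``
    with ``Ibar1 = I1*I3^(-1/3)``, ``Ibar2 = I2*I3^(-2/3)``,
    ``Ibar3 = sqrt(I3) = J`` (the volume ratio).
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("non-positive Jacobian: element inversion")
    C = np.swapaxes(F, -1, -2) @ F
    I1, I2, I3 = _mr_invariants(C)
    Ib1 = I1 * I3 ** (-1.0 / 3.0)
    Ib2 = I2 * I3 ** (-2.0 / 3.0)
    Ib3 = np.sqrt(I3)
    return (
        p.a10 * (Ib1 - 3.0)
        + p.a01 * (Ib2 - 3.0)
        + 0.5 * p.bulk * (Ib3 - 1.0) ** 2
    )


def aponeurosis_pk2(F, p: AponeurosisParams):
    """PK2 stress ``S = 2 dW/dC`` of the Mooney-Rivlin law (analytic)."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("non-positive Jacobian: element inversion")
    C = np.swapaxes(F, -1, -2) @ F
    I1, I2, I3 = _mr_invariants(C)
    Cinv = np.linalg.inv(C)
    eye = np.broadcast_to(np.eye(3), C.shape)
    I1e = I1[..., None, None]
    I2e = I2[..., None, None]
    I3e = I3[..., None, None]
    Je = np.sqrt(I3e)
    dIb1 = I3e ** (-1.0 / 3.0) * (eye - (I1e / 3.0) * Cinv)
    dIb2 = I3e ** (-2.0 / 3.0) * (I1e * eye - C - (2.0 * I2e / 3.0) * Cinv)
    dIb3 = 0.5 * Je * Cinv
    return 2.0 * (
        p.a10 * dIb1 + p.a01 * dIb2 + p.bulk * (Je - 1.0) * dIb3
    )
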