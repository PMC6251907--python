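"""Leaflet and chordal constitutive laws.

Leaflet tissue is modeled as a fiber-reinforced, nearly incompressible
hyperelastic solid of modified Holzapfel--Gasser--Ogden (MHGO) type with two
dispersed collagen-fiber families:

.. math::

    W = C_{10}\\{\\exp[C_{01}(\\bar I_1 - 3)] - 1\\}
        + \\frac{k_1}{2 k_2} \\sum_{i=1}^{2}
          \\{\\exp(k_2 [\\kappa \\bar I_1 + (1 - 3\\kappa)\\bar I_{4i} - 1]^2) - 1\\}
        + \\frac{1}{D}(J - 1)^2

where :math:`\\bar I_1 = \\mathrm{tr}\\,\\bar C`,
:math:`\\bar I_{4i} = m_i \\cdot \\bar C m_i` are deviatoric invariants of
:math:`\\bar C = J^{-2/3} F^T F`, :math:`m_i` are the reference fiber
directions, and :math:`\\kappa \\in [0, 1/3]` is the fiber-dispersion
parameter (:math:`\\kappa = 1/3` is an isotropic fiber distribution).  The
exponential matrix term describes the non-collagenous ground substance, the
fiber sum the collagen response, and the quadratic :math:`J` term weakly
enforces incompressibility.

By the usual convention for collagen, a fiber family contributes only when
its dispersed pseudo-invariant argument
:math:`\\kappa\\bar I_1 + (1-3\\kappa)\\bar I_{4i} - 1` is positive (fibers do
not support compression); the switch can be disabled per parameter set.

Chordae tendineae are one-dimensional tension-only members following an
incompressible isotropic Ogden law,
:math:`W = \\sum_p 2\\mu_p/\\alpha_p^2\\,
(\\lambda_1^{\\alpha_p}+\\lambda_2^{\\alpha_p}+\\lambda_3^{\\alpha_p}-3)`.

All stresses are in MPa, forces in N, areas in mm^2 (MPa x mm^2 = N).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    EmptyRegionError,
    InvalidDeformationError,
    ParameterDomainError,
    ValidationError,
)

__all__ = [
    "MaterialParamsMHGO",
    "DeformationState",
    "OgdenParams",
    "StressResult",
    "deviatoric_invariants",
    "strain_energy_mhgo",
    "stress_mhgo",
    "ogden_chord_force",
    "ogden_nominal_stress",
    "max_principal_stress",
    "region_average",
    "fiber_directions_from_angle",
    "uniaxial_incompressible_stress",
    "EXAMPLE_LEAFLET_PARAMS",
    "EXAMPLE_OGDEN_PARAMS",
]

_EXCLUDED_LABELS = frozenset({"coaptation", "annulus"})


def fiber_directions_from_angle(angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Two symmetric fiber families at ``+/- angle_deg`` about the local
    circumferential (x) axis, in the leaflet tangent (x-y) plane."""
    a = math.radians(angle_deg)
    m1 = np.array([math.cos(a), math.sin(a), 0.0])
    m2 = np.array([math.cos(a), -math.sin(a), 0.0])
    return m1, m2


@dataclass(frozen=True)
class MaterialParamsMHGO:
    """Constants of the MHGO leaflet strain-energy function.

    Parameters
    ----------
    c10 : float
        Ground-matrix stress-like constant, MPa. Must be positive.
    c01 : float
        Ground-matrix exponential rate, dimensionless.
    k1 : float
        Fiber stiffness, MPa. Non-negative.
    k2 : float
        Fiber exponential rate, dimensionless, positive.
    kappa : float
        Fiber-dispersion parameter in [0, 1/3].
    d_incomp : float
        Volumetric penalty constant D, 1/MPa, positive; the volumetric
        energy is (1/D)(J-1)^2.
    fiber_angle_deg : float
        Half-angle of the two symmetric fiber families about the local
        circumferential axis, degrees.
    fiber_tension_only : bool
        If True (default), a fiber family is switched off whenever its
        dispersed pseudo-invariant argument is non-positive.
    """

    c10: float
    c01: float
    k1: float
    k2: float
    kappa: float
    d_incomp: float
    fiber_angle_deg: float = 0.0
    fiber_tension_only: bool = True

    def __post_init__(self) -> None:
        if not self.c10 > 0:
            raise ParameterDomainError(f"c10 must be > 0, got {self.c10}")
        if self.k1 < 0:
            raise ParameterDomainError(f"k1 must be >= 0, got {self.k1}")
        if not self.k2 > 0:
            raise ParameterDomainError(f"k2 must be > 0, got {self.k2}")
        if not 0.0 <= self.kappa <= 1.0 / 3.0 + 1e-15:
            raise ParameterDomainError(f"kappa must lie in [0, 1/3], got {self.kappa}")
        if not self.d_incomp > 0:
            raise ParameterDomainError(f"d_incomp must be > 0, got {self.d_incomp}")

    def fiber_directions(self) -> tuple[np.ndarray, np.ndarray]:
        return fiber_directions_from_angle(self.fiber_angle_deg)

    @classmethod
    def from_json(cls, path: str | Path) -> "MaterialParamsMHGO":
        """Load from a JSON file with keys c10, c01, k1, k2, kappa,
        d_incomp, fiber_angle_deg (units MPa / degrees)."""
        data = json.loads(Path(path).read_text())
        return cls(
            c10=float(data["c10"]),
            c01=float(data["c01"]),
            k1=float(data["k1"]),
            k2=float(data["k2"]),
            kappa=float(data["kappa"]),
            d_incomp=float(data["d_incomp"]),
            fiber_angle_deg=float(data.get("fiber_angle_deg", 0.0)),
            fiber_tension_only=bool(data.get("fiber_tension_only", True)),
        )


@dataclass(frozen=True)
class DeformationState:
    """A deformation gradient plus the two reference fiber directions."""

    deformation_gradient: np.ndarray
    fiber_dirs: tuple[np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        F = np.asarray(self.deformation_gradient, dtype=float)
        if F.shape != (3, 3):
            raise ValidationError(f"deformation gradient must be 3x3, got {F.shape}")
        object.__setattr__(self, "deformation_gradient", F)
        if np.linalg.det(F) <= 0:
            raise InvalidDeformationError(
                f"det F = {np.linalg.det(F):.6g} must be positive"
            )
        dirs = tuple(np.asarray(m, dtype=float) for m in self.fiber_dirs)
        if len(dirs) != 2:
            raise ValidationError("exactly two fiber directions required")
        for m in dirs:
            if abs(np.linalg.norm(m) - 1.0) > 1e-12:
                raise ValidationError(f"fiber direction {m} is not unit norm")
        object.__setattr__(self, "fiber_dirs", dirs)

    @classmethod
    def from_gradient(
        cls, F: np.ndarray, params: MaterialParamsMHGO
    ) -> "DeformationState":
        return cls(np.asarray(F, dtype=float), params.fiber_directions())


@dataclass(frozen=True)
class OgdenParams:
    """Terms ``(mu_p [MPa], alpha_p)`` of an incompressible Ogden solid.

    The ground-state shear modulus is positive iff ``sum(mu_p * alpha_p) > 0``.
    """

    terms: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        terms = tuple((float(m), float(a)) for m, a in self.terms)
        if len(terms) < 1:
            raise ParameterDomainError("Ogden model needs at least one term")
        if sum(m * a for m, a in terms) <= 0:
            raise ParameterDomainError(
                "sum(mu_p * alpha_p) must be positive for a stable ground state"
            )
        object.__setattr__(self, "terms", terms)

    @classmethod
    def from_json(cls, path: str | Path) -> "OgdenParams":
        """Load from JSON: a list of ``{"mu_MPa": ..., "alpha": ...}``."""
        data = json.loads(Path(path).read_text())
        return cls(tuple((t["mu_MPa"], t["alpha"]) for t in data))


@dataclass(frozen=True)
class StressResult:
    """Cauchy and second Piola-Kirchhoff stress (MPa) plus the strain energy
    density (MPa, per unit reference volume)."""

    cauchy: np.ndarray
    pk2: np.ndarray
    energy: float


# Documented example parameter sets for tests and demos. These are synthetic
# round numbers of leaflet-tissue magnitude, not fitted to any experiment.
EXAMPLE_LEAFLET_PARAMS = MaterialParamsMHGO(
    c10=0.05, c01=10.0, k1=1.0, k2=5.0, kappa=0.1, d_incomp=0.02, fiber_angle_deg=40.0
)
EXAMPLE_OGDEN_PARAMS = OgdenParams(terms=((10.0, 2.0),))


def deviatoric_invariants(
    state: DeformationState,
) -> tuple[float, tuple[float, float], float]:
    """Deviatoric invariants ``(i1bar, (i4bar_1, i4bar_2), J)`` of a state.

    ``i1bar = tr(J^{-2/3} F^T F)`` and ``i4bar_i = m_i . (J^{-2/3} F^T F) m_i``.
    """
    F = state.deformation_gradient
    J = float(np.linalg.det(F))
    if J <= 0:
        raise InvalidDeformationError(f"det F = {J:.6g} must be positive")
    Cbar = J ** (-2.0 / 3.0) * (F.T @ F)
    i1bar = float(np.trace(Cbar))
    i4 = tuple(float(m @ Cbar @ m) for m in state.fiber_dirs)
    return i1bar, (i4[0], i4[1]), J


def _fiber_arguments(
    i1bar: float, i4bar: Sequence[float], params: MaterialParamsMHGO
) -> list[float]:
    k = params.kappa
    return [k * i1bar + (1.0 - 3.0 * k) * i4 - 1.0 for i4 in i4bar]


def strain_energy_mhgo(state: DeformationState, params: MaterialParamsMHGO) -> float:
    """MHGO strain energy density W (MPa per unit reference volume)."""
    i1bar, i4bar, J = deviatoric_invariants(state)
    W = params.c10 * (math.exp(params.c01 * (i1bar - 3.0)) - 1.0)
    for E in _fiber_arguments(i1bar, i4bar, params):
        if params.fiber_tension_only and E <= 0.0:
            continue
        W += (
            params.k1
            / (2.0 * params.k2)
            * (math.exp(params.k2 * E * E) - 1.0)
        )
    W += (1.0 / params.d_incomp) * (J - 1.0) ** 2
    return W


def stress_mhgo(state: DeformationState, params: MaterialParamsMHGO) -> StressResult:
    """Analytic MHGO stress: PK2 = 2 dW/dC and Cauchy = J^-1 F PK2 F^T.

    The isochoric chain rule gives, with ``psi1 = dW/dI1bar`` and
    ``psi4i = dW/dI4bar_i``,

        PK2 = 2 [ psi1 (J^{-2/3} I - I1bar/3 C^-1)
                  + sum_i psi4i (J^{-2/3} m_i (x) m_i - I4bar_i/3 C^-1) ]
              + (2/D)(J-1) J C^-1
    """
    F = state.deformation_gradient
    i1bar, i4bar, J = deviatoric_invariants(state)
    C = F.T @ F
    Cinv = np.linalg.inv(C)
    I = np.eye(3)

    Es = _fiber_arguments(i1bar, i4bar, params)
    psi1 = params.c10 * params.c01 * math.exp(params.c01 * (i1bar - 3.0))
    psi4 = [0.0, 0.0]
    for i, E in enumerate(Es):
        if params.fiber_tension_only and E <= 0.0:
            continue
        g = params.k1 * E * math.exp(params.k2 * E * E)
        psi1 += g * params.kappa
        psi4[i] = g * (1.0 - 3.0 * params.kappa)

    Jm23 = J ** (-2.0 / 3.0)
    S = psi1 * (Jm23 * I - (i1bar / 3.0) * Cinv)
    for i, m in enumerate(state.fiber_dirs):
        if psi4[i] != 0.0:
            S = S + psi4[i] * (Jm23 * np.outer(m, m) - (i4bar[i] / 3.0) * Cinv)
    S = 2.0 * S
    S = S + (2.0 / params.d_incomp) * (J - 1.0) * J * Cinv

    cauchy = (F @ S @ F.T) / J
    cauchy = 0.5 * (cauchy + cauchy.T)  # symmetrize round-off
    energy = strain_energy_mhgo(state, params)
    return StressResult(cauchy=cauchy, pk2=0.5 * (S + S.T), energy=energy)


def ogden_nominal_stress(stretch: float, params: OgdenParams) -> float:
    """Nominal (first Piola) uniaxial stress of an incompressible Ogden solid
    at the given axial stretch, MPa.

    With lateral stretches ``stretch**-0.5``,
    ``P = sum_p (2 mu_p / alpha_p) (stretch^(alpha_p - 1)
    - stretch^(-alpha_p/2 - 1))``.
    """
    if stretch <= 0:
        raise InvalidDeformationError(f"stretch must be positive, got {stretch}")
    lam = float(stretch)
    return sum(
        (2.0 * mu / a) * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
        for mu, a in params.terms
    )


def ogden_chord_force(stretch: float, params: OgdenParams, area0: float) -> float:
    """Axial force (N) in a tension-only chord of reference cross-section
    ``area0`` mm^2 at the given stretch; zero for slack (stretch <= 1)."""
    if stretch <= 0:
        raise InvalidDeformationError(f"stretch must be positive, got {stretch}")
    if area0 <= 0:
        raise ParameterDomainError(f"area0 must be positive, got {area0}")
    if stretch <= 1.0:
        return 0.0
    return area0 * ogden_nominal_stress(stretch, params)


def max_principal_stress(stress: np.ndarray, *, tol: float = 1e-8) -> float:
    """Largest principal value (eigenvalue) of a symmetric stress tensor."""
    s = np.asarray(stress, dtype=float)
    if s.shape != (3, 3):
        raise ValidationError(f"stress must be 3x3, got shape {s.shape}")
    scale = max(1.0, float(np.abs(s).max()))
    if np.abs(s - s.T).max() > tol * scale:
        raise ValidationError("stress tensor is not symmetric within tolerance")
    return float(np.linalg.eigvalsh(0.5 * (s + s.T))[-1])


def region_average(
    values: Sequence[float],
    region_labels: Sequence[str],
    region: str,
    *,
    excluded: Sequence[str] | None = None,
) -> float:
    """Mean of ``values`` whose label equals ``region``.

    Entries labeled as coaptation or annulus (or any label in ``excluded``)
    never contribute: those zones are load-transfer artifacts, not leaflet
    belly material response.
    """
    if len(values) != len(region_labels):
        raise ValidationError("values and region_labels must have equal length")
    skip = _EXCLUDED_LABELS if excluded is None else frozenset(excluded)
    sel = [
        v
        for v, lab in zip(values, region_labels)
        if lab == region and lab not in skip
    ]
    if not sel:
        raise EmptyRegionError(f"no admissible entries for region {region!r}")
    return float(np.mean(sel))


def uniaxial_incompressible_stress(
    stretch: float, params: MaterialParamsMHGO, *, fibers_along_stretch: bool = True
) -> float:
    """Closed-form uniaxial Cauchy stress under exact incompressibility.

    The Lagrange pressure is eliminated by the traction-free lateral faces:
    ``sigma_axial = lam dW_iso/dlam`` evaluated on
    F = diag(lam, lam^-1/2, lam^-1/2).  Used by tests as an independent
    cross-check of the penalty formulation at large D^-1; not part of the
    solver path.
    """
    if stretch <= 0:
        raise InvalidDeformationError("stretch must be positive")
    lam = float(stretch)
    # finite-difference of the isochoric energy along the incompressible path
    h = 1e-7 * lam

    def w(l: float) -> float:
        F = np.diag([l, l ** -0.5, l ** -0.5])
        dirs = (
            (np.array([1.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]))
            if fibers_along_stretch
            else fiber_directions_from_angle(params.fiber_angle_deg)
        )
        return strain_energy_mhgo(DeformationState(F, dirs), params)

    return lam * (w(lam + h) - w(lam - h)) / (2.0 * h)
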