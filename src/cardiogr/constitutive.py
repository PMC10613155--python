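"""Constituent strain energies, fiber stresses, and the mixture stress.

Kinematics follow the multiplicative split ``F = F_e^i F_r^i`` per constituent:
the total deformation gradient is shared by all constituents of the mixture,
while each fiber constituent carries its own inelastic remodeling stretch
``lambda_r`` (rank-one-plus-isotropic, unit determinant).  The mixture first
Piola-Kirchhoff stress is the rule-of-mixtures sum of the constituent
contributions plus a volumetric penalty that ties det F to the referential
mass ratio (growth).

Stress conventions
------------------
Two stress measures appear:

* the *mixture* first Piola-Kirchhoff stress ``P`` (force per reference area
  of the mixture) that enters mechanical equilibrium, and
* the *constituent fiber Cauchy stress* ``sigma^i`` that drives mass turnover
  and remodeling.  We use the intensive convention

  ``sigma^i = 2 rho0_total(0) I4e dW^i/dI4e  (+ sigma_act_max f(lambda_act)
  for myocytes)``,

  i.e. the partial mixture Cauchy stress divided by the constituent's volume
  fraction at constant true density.  With this convention the homeostatic set
  point is purely strain-driven and the myocyte value at the homeostatic
  elastic stretch 1.1 is calibrated to 22 kPa via the initial active stretch.

Batch kernels operate on arrays of deformation gradients ``F`` with shape
``(n, 3, 3)`` and per-point constituent fields; they return the stress and the
consistent tangent ``A = dP/dF`` used by the finite element solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ElastinParams, FiberConstituentParams, MixtureParams

__all__ = [
    "DeformationState",
    "fiber_elastic_invariant",
    "fung_fiber_energy_and_derivative",
    "active_stress_factor",
    "active_fiber_stress",
    "elastin_cauchy_stress",
    "volumetric_penalty_stress",
    "constituent_fiber_cauchy_stress",
    "mixture_first_pk_stress",
    "PointFields",
    "mixture_pk_batch",
    "mixture_energy_batch",
    "fiber_stress_batch",
]

_I3 = np.eye(3)


# ---------------------------------------------------------------------------
# scalar (single material point) operations
# ---------------------------------------------------------------------------

@dataclass
class DeformationState:
    """Deformation data of one material point.

    ``f0`` are unit fiber directions in the reference configuration (one per
    fiber constituent), ``lambda_r`` the corresponding remodeling stretches,
    and ``G3D`` the symmetric unit-determinant elastin prestretch tensor.
    """

    F: np.ndarray
    f0: np.ndarray  # (n_fib, 3)
    lambda_r: np.ndarray  # (n_fib,)
    G3D: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.f0 = np.atleast_2d(np.asarray(self.f0, dtype=float))
        self.lambda_r = np.atleast_1d(np.asarray(self.lambda_r, dtype=float))
        self.G3D = np.asarray(self.G3D, dtype=float)
        if np.linalg.det(self.F) <= 0:
            raise ValueError("deformation gradient must have positive determinant")
        if np.any(np.abs(np.linalg.norm(self.f0, axis=1) - 1.0) > 1e-8):
            raise ValueError("fiber directions must be unit vectors")
        if np.any(self.lambda_r <= 0):
            raise ValueError("remodeling stretches must be positive")
        if abs(np.linalg.det(self.G3D) - 1.0) > 1e-8:
            raise ValueError("elastin prestretch must have unit determinant")
        if not np.allclose(self.G3D, self.G3D.T, atol=1e-10):
            raise ValueError("elastin prestretch must be symmetric")


def fiber_elastic_invariant(F: np.ndarray, f0: np.ndarray, lambda_r: float) -> float:
    """Fourth pseudo-invariant of the elastic deformation of a fiber.

    With the rank-one remodeling gradient, the fiber direction is an
    eigenvector of ``F_r`` and ``I4e = (f0 . C f0) / lambda_r^2``.
    """
    F = np.asarray(F, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if np.linalg.det(F) <= 0:
        raise ValueError("deformation gradient must have positive determinant")
    if abs(np.linalg.norm(f0) - 1.0) > 1e-8:
        raise ValueError("fiber direction must be a unit vector")
    if lambda_r <= 0:
        raise ValueError("remodeling stretch must be positive")
    v = F @ f0
    return float(v @ v) / (lambda_r * lambda_r)


def fung_fiber_energy_and_derivative(
    I4e: float, p: FiberConstituentParams
) -> tuple[float, float]:
    """Fung exponential fiber energy per unit mass and its I4e-derivative.

    Tension-only: both vanish for ``I4e < 1`` (fibers are excluded during
    compression).
    """
    if I4e <= 0:
        raise ValueError("elastic invariant must be positive")
    if I4e < 1.0:
        return 0.0, 0.0
    x = I4e - 1.0
    e = np.exp(p.b * x * x)
    W = p.a / (2.0 * p.b) * (e - 1.0)
    dW = p.a * x * e
    return float(W), float(dW)


def active_stress_factor(lambda_act: float, p: FiberConstituentParams) -> float:
    """Normalized active-tone factor in [0, 1], zero at ``lambda_0`` and one at
    ``lambda_max`` (clamped outside the physiological range)."""
    lam = min(max(lambda_act, p.lambda_0), p.lambda_max)
    q = (p.lambda_max - lam) / (p.lambda_max - p.lambda_0)
    return 1.0 - q * q


def active_fiber_stress(
    lambda_act: float, rho_ratio: float, p: FiberConstituentParams
) -> float:
    """Active fiber Cauchy stress contribution (Pa).

    ``rho_ratio`` scales the stress with the constituent's mass content,
    ``rho0^m(s)/rho0_total(0)`` (the active strain energy is normalized by
    the total mixture density, so the stress carries the myocyte mass
    fraction; at time 0 this is ``xi0^m``).
    """
    return rho_ratio * p.sigma_act_max * active_stress_factor(lambda_act, p)


def elastin_cauchy_stress(
    F: np.ndarray, G3D: np.ndarray, e: ElastinParams, rho_e: float
) -> np.ndarray:
    """Deviatoric Cauchy stress of the prestretched neo-Hookean matrix."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if J <= 0:
        raise ValueError("deformation gradient must be invertible with det > 0")
    H = G3D @ G3D
    B = F @ H @ F.T
    t = np.trace(B)
    beta = J ** (-2.0 / 3.0)
    return 2.0 * rho_e * e.c1 * beta / J * (B - t / 3.0 * _I3)


def volumetric_penalty_stress(F: np.ndarray, mass_ratio: float, kappa: float) -> np.ndarray:
    """First Piola-Kirchhoff stress of the growth penalty
    ``Psi# = kappa/2 (J - rho0(s)/rho0(0))^2``; zero iff J equals the mass ratio."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if J <= 0:
        raise ValueError("deformation gradient must have positive determinant")
    if mass_ratio <= 0:
        raise ValueError("mass ratio must be positive")
    return kappa * (J - mass_ratio) * J * np.linalg.inv(F).T


def constituent_fiber_cauchy_stress(
    state: DeformationState,
    p: FiberConstituentParams,
    mixture: MixtureParams,
    rho_ratio: float | None = None,
    *,
    fiber_index: int = 0,
    lambda_act: float | None = None,
) -> float:
    """Intensive fiber-direction Cauchy stress of one constituent.

    Passive part ``2 rho0_total(0) I4e dW/dI4e`` plus, for myocytes, the active
    tone at the current active stretch.  This is the quantity compared with the
    homeostatic set point ``sigma_h`` in the turnover and remodeling laws.
    """
    I4e = fiber_elastic_invariant(state.F, state.f0[fiber_index], state.lambda_r[fiber_index])
    _, dW = fung_fiber_energy_and_derivative(I4e, p)
    sigma = 2.0 * mixture.rho0_total * I4e * dW
    if p.is_active:
        if lambda_act is None:
            lambda_act = mixture.lambda_act0
        if rho_ratio is None:
            rho_ratio = p.xi0  # initial myocyte mass fraction
        sigma += active_fiber_stress(lambda_act, rho_ratio, p)
    return float(sigma)


# ---------------------------------------------------------------------------
# batch kernels (struct-of-arrays over Gauss points)
# ---------------------------------------------------------------------------

@dataclass
class PointFields:
    """Evolving per-point constituent fields for a batch of material points.

    ``rho0`` and ``lambda_r`` have shape ``(n, n_fib)`` with the myocyte in
    column 0 followed by the collagen families; ``f0`` has shape
    ``(n, n_fib, 3)``; ``G3D`` has shape ``(n, 3, 3)``.  ``rho0_elastin`` is
    constant in time (elastin does not remodel).
    """

    rho0: np.ndarray
    lambda_r: np.ndarray
    f0: np.ndarray
    G3D: np.ndarray
    rho0_elastin: np.ndarray

    @classmethod
    def homeostatic(
        cls, f0: np.ndarray, mix: MixtureParams, *, prestretch_scale: float = 1.0
    ) -> "PointFields":
        """Initialize at the prestressed homeostatic state: ``lambda_r = 1 /
        lambda_h`` so the elastic fiber stretch at F = I equals ``lambda_h``.

        ``prestretch_scale`` in [0, 1] ramps the homeostatic prestretch
        linearly (used while ramping loads during prestressing).
        """
        n = f0.shape[0]
        lam_h = np.array(
            [1.0 + prestretch_scale * (f.lambda_h - 1.0) for f in mix.fibers]
        )
        rho0 = np.tile([f.xi0 * mix.rho0_total for f in mix.fibers], (n, 1))
        lam_r = np.tile(1.0 / lam_h, (n, 1))
        return cls(
            rho0=rho0,
            lambda_r=lam_r,
            f0=np.asarray(f0, dtype=float),
            G3D=np.tile(_I3, (n, 1, 1)),
            rho0_elastin=np.full(n, mix.rho0_elastin),
        )

    @property
    def n_points(self) -> int:
        return self.rho0.shape[0]

    def mass_ratio(self, mix: MixtureParams) -> np.ndarray:
        """Referential mass ratio ``rho0(s)/rho0(0)`` per point."""
        return (self.rho0.sum(axis=1) + self.rho0_elastin) / mix.rho0_total

    def copy(self) -> "PointFields":
        return PointFields(
            self.rho0.copy(),
            self.lambda_r.copy(),
            self.f0,
            self.G3D.copy(),
            self.rho0_elastin.copy(),
        )


def _fung_dW(i4e: np.ndarray, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized dW/dI4e and d2W/dI4e2 with the tension-only switch."""
    x = np.maximum(i4e - 1.0, 0.0)
    e = np.exp(b * x * x)
    dW = a * x * e
    d2W = a * e * (1.0 + 2.0 * b * x * x)
    d2W = np.where(i4e >= 1.0, d2W, 0.0)
    return dW, d2W


def _active_terms(
    i4: np.ndarray, i4e: np.ndarray, mix: MixtureParams, active_scale: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Active stretch, dWact/dlam_act (per unit mass) and its lam_act-derivative.

    The active stretch evolves with ``d(lambda_act)/d(lambda) = 1/lambda``
    from its calibrated initial value.  With ``active_reference = "total"``
    (default) the driving stretch is the total fiber stretch relative to the
    reference configuration, ``lambda_act = lambda_act0 + ln(sqrt(I4))``;
    with ``"elastic"`` it is the elastic stretch relative to the evolving
    stress-free configuration, ``lambda_act0 + ln(sqrt(I4e)/lambda_h)``, so
    turnover re-adapts the tone toward its baseline.
    """
    p = mix.myocyte
    if mix.active_reference == "total":
        lam_act = mix.lambda_act0 + 0.5 * np.log(i4)
    else:
        lam_act = mix.lambda_act0 + 0.5 * np.log(i4e / p.lambda_h**2)
    lam_cl = np.clip(lam_act, p.lambda_0, p.lambda_max)
    q = (p.lambda_max - lam_cl) / (p.lambda_max - p.lambda_0)
    smax = active_scale * p.sigma_act_max / mix.rho0_total
    dW = smax * (1.0 - q * q)
    d2W = np.where(
        (lam_act > p.lambda_0) & (lam_act < p.lambda_max),
        smax * 2.0 * q / (p.lambda_max - p.lambda_0),
        0.0,
    )
    return lam_act, dW, d2W


def fiber_stress_batch(
    F: np.ndarray,
    fields: PointFields,
    mix: MixtureParams,
    *,
    active_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intensive fiber Cauchy stresses and elastic stiffnesses per constituent.

    Returns ``(sigma, dsigma_dI4e, I4e)``, each of shape ``(n, n_fib)``.
    ``dsigma_dI4e`` is the passive elastic stiffness entering the remodeling
    ODE (the active tone does not depend on the elastic stretch).
    """
    Ff = np.einsum("nij,nfj->nfi", F, fields.f0)
    i4 = np.einsum("nfi,nfi->nf", Ff, Ff)
    i4e = i4 / fields.lambda_r**2
    rho_hat = mix.rho0_total
    sigma = np.empty_like(i4e)
    dsig = np.empty_like(i4e)
    for c, p in enumerate(mix.fibers):
        dW, d2W = _fung_dW(i4e[:, c], p.a, p.b)
        sigma[:, c] = 2.0 * rho_hat * i4e[:, c] * dW
        dsig[:, c] = 2.0 * rho_hat * (dW + i4e[:, c] * d2W)
    # myocyte active tone (column 0), scaled by the evolving mass fraction
    _, dWact, d2Wact = _active_terms(i4[:, 0], i4e[:, 0], mix, active_scale)
    sigma[:, 0] += fields.rho0[:, 0] * dWact
    if mix.active_reference == "elastic":
        # in the elastic mode the tone depends on I4e and contributes to the
        # remodeling stiffness
        dsig[:, 0] += fields.rho0[:, 0] * d2Wact / (2.0 * i4e[:, 0])
    return sigma, dsig, i4e


def mixture_pk_batch(
    F: np.ndarray,
    fields: PointFields,
    mix: MixtureParams,
    *,
    active_scale: float = 1.0,
    with_tangent: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Mixture first Piola-Kirchhoff stress and consistent tangent dP/dF.

    ``F`` has shape ``(n, 3, 3)``.  Contributions: passive Fung fibers
    (tension only), myocyte active tone, prestretched isochoric neo-Hookean
    elastin, and the volumetric growth penalty.
    """
    n = F.shape[0]
    P = np.zeros((n, 3, 3))
    A = np.zeros((n, 3, 3, 3, 3)) if with_tangent else None

    Ff = np.einsum("nij,nfj->nfi", F, fields.f0)  # (n, nf, 3)
    i4 = np.einsum("nfi,nfi->nf", Ff, Ff)
    lr2 = fields.lambda_r**2
    i4e = i4 / lr2

    for c, p in enumerate(mix.fibers):
        dW, d2W = _fung_dW(i4e[:, c], p.a, p.b)
        rho = fields.rho0[:, c]
        coef = 2.0 * rho * dW / lr2[:, c]
        FM = Ff[:, c, :, None] * fields.f0[:, c, None, :]  # (F f0) otimes f0
        P += coef[:, None, None] * FM
        if with_tangent:
            M = fields.f0[:, c, :, None] * fields.f0[:, c, None, :]
            dcoef = 4.0 * rho * d2W / lr2[:, c] ** 2
            IxM = _I3[None, :, None, :, None] * M[:, None, :, None, :]
            FMxFM = FM[:, :, :, None, None] * FM[:, None, None, :, :]
            A += coef[:, None, None, None, None] * IxM
            A += dcoef[:, None, None, None, None] * FMxFM
        if p.is_active:
            _, dWact, d2Wact = _active_terms(i4[:, c], i4e[:, c], mix, active_scale)
            d = rho * dWact / i4[:, c]
            P += d[:, None, None] * FM
            if with_tangent:
                dd = rho * (0.5 * d2Wact - dWact) / i4[:, c] ** 2
                A += d[:, None, None, None, None] * IxM
                A += 2.0 * dd[:, None, None, None, None] * FMxFM

    # elastin: P = k1 (2 beta F H - 2/3 beta t F^-T)
    k1 = fields.rho0_elastin * mix.elastin.c1
    J = np.linalg.det(F)
    FiT = np.linalg.inv(F).transpose(0, 2, 1)
    H = np.einsum("nij,njk->nik", fields.G3D, fields.G3D)
    FH = np.einsum("nij,njk->nik", F, H)
    t = np.einsum("nij,nij->n", F, FH)
    beta = J ** (-2.0 / 3.0)
    kb = k1 * beta
    P += 2.0 * kb[:, None, None] * FH - (2.0 / 3.0) * (kb * t)[:, None, None] * FiT
    if with_tangent:
        def _ox(X, Y):
            return X[:, :, :, None, None] * Y[:, None, None, :, :]

        A += 2.0 * kb[:, None, None, None, None] * (
            _I3[None, :, None, :, None] * H[:, None, :, None, :]
        )
        A -= (4.0 / 3.0) * kb[:, None, None, None, None] * (_ox(FH, FiT) + _ox(FiT, FH))
        A += (4.0 / 9.0) * (kb * t)[:, None, None, None, None] * _ox(FiT, FiT)
        # d(F^-T)/dF term: -FiT_iL FiT_kJ
        A += (2.0 / 3.0) * (kb * t)[:, None, None, None, None] * np.einsum(
            "nil,nkj->nijkl", FiT, FiT, optimize=True
        )

    # volumetric growth penalty
    m = fields.mass_ratio(mix)
    g = mix.kappa * (J - m)
    P += (g * J)[:, None, None] * FiT
    if with_tangent:
        A += (mix.kappa * (2.0 * J - m) * J)[:, None, None, None, None] * (
            FiT[:, :, :, None, None] * FiT[:, None, None, :, :]
        )
        A -= (g * J)[:, None, None, None, None] * np.einsum(
            "nil,nkj->nijkl", FiT, FiT, optimize=True
        )

    return P, A


def mixture_energy_batch(
    F: np.ndarray,
    fields: PointFields,
    mix: MixtureParams,
    *,
    active_scale: float = 1.0,
) -> np.ndarray:
    """Total strain energy per unit reference volume (for gradient checks)."""
    Ff = np.einsum("nij,nfj->nfi", F, fields.f0)
    i4 = np.einsum("nfi,nfi->nf", Ff, Ff)
    i4e = i4 / fields.lambda_r**2
    psi = np.zeros(F.shape[0])
    for c, p in enumerate(mix.fibers):
        x = np.maximum(i4e[:, c] - 1.0, 0.0)
        W = p.a / (2.0 * p.b) * (np.exp(p.b * x * x) - 1.0)
        psi += fields.rho0[:, c] * W
        if p.is_active:
            lam_act, _, _ = _active_terms(i4[:, c], i4e[:, c], mix, active_scale)
            lam_cl = np.clip(lam_act, p.lambda_0, p.lambda_max)
            smax = active_scale * p.sigma_act_max / mix.rho0_total
            Wact = smax * (
                lam_cl
                + (p.lambda_max - lam_cl) ** 3 / (3.0 * (p.lambda_max - p.lambda_0) ** 2)
            )
            # outside the clamp range the stress is constant in lambda_act;
            # extend the energy linearly to keep it consistent with the stress
            Wact += smax * np.where(lam_act > p.lambda_max, lam_act - p.lambda_max, 0.0)
            psi += fields.rho0[:, c] * Wact
    J = np.linalg.det(F)
    H = np.einsum("nij,njk->nik", fields.G3D, fields.G3D)
    t = np.einsum("nij,nik,njk->n", F, F, H)
    psi += fields.rho0_elastin * mix.elastin.c1 * (J ** (-2.0 / 3.0) * t - 3.0)
    psi += 0.5 * mix.kappa * (J - fields.mass_ratio(mix)) ** 2
    return psi


def mixture_first_pk_stress(
    F: np.ndarray,
    fields_or_state: "PointFields | DeformationState",
    mix: MixtureParams,
    *,
    active_scale: float = 1.0,
) -> np.ndarray:
    """Mixture first Piola-Kirchhoff stress at a single material point."""
    if isinstance(fields_or_state, DeformationState):
        st = fields_or_state
        n_fib = st.f0.shape[0]
        fields = PointFields(
            rho0=np.array([[f.xi0 * mix.rho0_total for f in mix.fibers[:n_fib]]]),
            lambda_r=st.lambda_r[None, :],
            f0=st.f0[None, :, :],
            G3D=st.G3D[None, :, :],
            rho0_elastin=np.array([mix.rho0_elastin]),
        )
    else:
        fields = fields_or_state
    P, _ = mixture_pk_batch(
        np.asarray(F, dtype=float)[None, :, :],
        fields,
        mix,
        active_scale=active_scale,
        with_tangent=False,
    )
    return P[0]
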