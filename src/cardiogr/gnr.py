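"""Turnover (mass) and remodeling (inelastic stretch) evolution equations.

Each fiber constituent grows or atrophies according to a stress-driven net
mass production rate and remodels by drifting its stress-free configuration
toward the homeostatic stress.  Degradation follows a Poisson process with
mean survival time ``T``; homeostasis (``sigma = sigma_h``) is an exact fixed
point of both equations.  Elastin neither grows nor remodels.

A mechanical analog of the remodeling law is a Maxwell element (nonlinear
spring + dashpot with rate ``rho_dot/rho + 1/T``) in parallel with a motor
unit exerting the homeostatic stress: at frozen total stretch, small stress
deviations relax exponentially with time constant ``T``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import PointFields, fiber_stress_batch
from .params import MixtureParams

__all__ = [
    "ConstituentState",
    "GnRStepConfig",
    "net_mass_production_rate",
    "degradation_rate",
    "remodeling_rate",
    "remodeling_gradient",
    "active_stretch_update",
    "step_gnr",
    "step_gnr_batch",
]


@dataclass
class ConstituentState:
    """Evolving state of one fiber constituent at one material point."""

    rho0: float
    lambda_r: float
    sigma_h: float
    lambda_act: float | None = None

    def __post_init__(self) -> None:
        if self.rho0 <= 0 or self.lambda_r <= 0:
            raise ValueError("density and remodeling stretch must be positive")
        if self.sigma_h <= 0:
            raise ValueError("homeostatic stress must be positive")


@dataclass
class GnRStepConfig:
    """Time integration settings for the local evolution equations.

    The default step is a twentieth of the smallest mean survival time.
    """

    dt: float  # day
    scheme: str = "forward-euler"  # or "trapezoidal"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if self.scheme not in ("forward-euler", "trapezoidal"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @classmethod
    def default_for(cls, mix: MixtureParams, scheme: str = "forward-euler") -> "GnRStepConfig":
        t_min = min(f.T_survival for f in mix.fibers)
        return cls(dt=t_min / 20.0, scheme=scheme)


def net_mass_production_rate(
    rho0: float, k_gain: float, sigma: float, sigma_h: float
) -> float:
    """Net referential mass production rate (kg/m^3/day):
    ``rho0 k (sigma - sigma_h)/sigma_h``."""
    if sigma_h <= 0:
        raise ValueError("homeostatic stress must be positive")
    return rho0 * k_gain * (sigma - sigma_h) / sigma_h


def degradation_rate(rho0: float, T: float) -> float:
    """True mass degradation rate ``-rho0/T`` of the Poisson survival process."""
    if T <= 0:
        raise ValueError("mean survival time must be positive")
    return -rho0 / T


def remodeling_rate(
    state: ConstituentState,
    sigma: float,
    dsigma_dI4: float,
    I4e: float,
    rho_dot: float,
    T: float,
) -> float:
    """Rate of the inelastic remodeling stretch (1/day).

    ``lambda_r_dot = [rho_dot/rho0 + 1/T] lambda_r/(2 I4e) (dsigma/dI4e)^-1
    (sigma - sigma_h)``.  During compression the fiber stiffness vanishes; the
    rate is then set to zero (the stress-free configuration of a slack fiber
    cannot be inferred from stress).
    """
    if dsigma_dI4 <= 0.0:
        if sigma != state.sigma_h:
            import warnings

            warnings.warn("degenerate remodeling: zero fiber stiffness with "
                          "a stress mismatch (compressed fiber)")
        return 0.0
    return (
        (rho_dot / state.rho0 + 1.0 / T)
        * state.lambda_r
        / (2.0 * I4e)
        / dsigma_dI4
        * (sigma - state.sigma_h)
    )


def remodeling_gradient(lambda_r: float, f0: np.ndarray) -> np.ndarray:
    """Rank-one-plus-isotropic remodeling gradient, unit determinant:
    ``F_r = lambda_r f0 f0^T + lambda_r^{-1/2} (I - f0 f0^T)``."""
    if lambda_r <= 0:
        raise ValueError("remodeling stretch must be positive")
    f0 = np.asarray(f0, dtype=float)
    M = np.outer(f0, f0)
    return lambda_r * M + (np.eye(3) - M) / np.sqrt(lambda_r)


def active_stretch_update(
    lambda_act: float,
    lambda_total_old: float,
    lambda_total_new: float,
    *,
    mode: str = "additive-log",
) -> float:
    """Advance the active stretch with the total fiber stretch.

    The stated evolution ``d(lambda_act)/d(lambda) = 1/lambda`` integrates to
    an additive log increment (default).  ``mode='proportional'`` implements
    the alternative ``d(lambda_act)/d(lambda) = lambda_act/lambda`` found
    elsewhere in the literature.
    """
    if lambda_total_old <= 0 or lambda_total_new <= 0:
        raise ValueError("stretches must be positive")
    if mode == "additive-log":
        return lambda_act + float(np.log(lambda_total_new / lambda_total_old))
    if mode == "proportional":
        return lambda_act * lambda_total_new / lambda_total_old
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

def _rates(
    rho0: np.ndarray,
    lam_r: np.ndarray,
    i4_total: np.ndarray,
    active_sigma: np.ndarray,
    sigma_h: np.ndarray,
    mix: MixtureParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized net mass and remodeling rates at frozen total kinematics.

    ``i4_total`` is the total (inelastic + elastic) squared fiber stretch per
    constituent, constant during the local step; ``active_sigma`` is the
    myocyte active stress contribution, also frozen within the step.
    """
    i4e = i4_total / lam_r**2
    rho_hat = mix.rho0_total
    sigma = np.empty_like(i4e)
    dsig = np.empty_like(i4e)
    for c, p in enumerate(mix.fibers):
        x = np.maximum(i4e[:, c] - 1.0, 0.0)
        e = np.exp(p.b * x * x)
        dW = p.a * x * e
        d2W = np.where(i4e[:, c] >= 1.0, p.a * e * (1.0 + 2.0 * p.b * x * x), 0.0)
        sigma[:, c] = 2.0 * rho_hat * i4e[:, c] * dW
        # floor the remodeling stiffness at its tension-side limit 2 rho a so
        # slack fibers (I4e < 1) remodel back toward tension instead of
        # freezing in an atrophy ratchet
        dsig[:, c] = np.maximum(
            2.0 * rho_hat * (dW + i4e[:, c] * d2W), 2.0 * rho_hat * p.a
        )
    sigma[:, 0] += active_sigma
    k = np.array([p.k_gain for p in mix.fibers])
    T = np.array([p.T_survival for p in mix.fibers])
    dev = (sigma - sigma_h) / sigma_h
    rho_dot = rho0 * k * dev
    with np.errstate(divide="ignore", invalid="ignore"):
        lr_dot = (
            (rho_dot / rho0 + 1.0 / T)
            * lam_r
            / (2.0 * i4e)
            / dsig
            * (sigma - sigma_h)
        )
    lr_dot = np.where(dsig > 0.0, lr_dot, 0.0)
    return rho_dot, lr_dot


def step_gnr_batch(
    rho0: np.ndarray,
    lam_r: np.ndarray,
    i4_total: np.ndarray,
    active_sigma: np.ndarray,
    sigma_h: np.ndarray,
    mix: MixtureParams,
    cfg: GnRStepConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance densities and remodeling stretches of all fiber constituents by
    one step at frozen total kinematics.  Returns the new (rho0, lambda_r)."""
    r_dot, l_dot = _rates(rho0, lam_r, i4_total, active_sigma, sigma_h, mix)
    if cfg.scheme == "forward-euler":
        rho_new = rho0 + cfg.dt * r_dot
        lam_new = lam_r + cfg.dt * l_dot
    else:  # implicit trapezoidal via fixed-point iteration
        rho_new, lam_new = rho0 + cfg.dt * r_dot, lam_r + cfg.dt * l_dot
        for _ in range(30):
            r_dot1, l_dot1 = _rates(rho_new, lam_new, i4_total, active_sigma, sigma_h, mix)
            rho_next = rho0 + 0.5 * cfg.dt * (r_dot + r_dot1)
            lam_next = lam_r + 0.5 * cfg.dt * (l_dot + l_dot1)
            delta = max(
                np.max(np.abs(rho_next - rho_new)) / max(np.max(np.abs(rho0)), 1.0),
                np.max(np.abs(lam_next - lam_new)),
            )
            rho_new, lam_new = rho_next, lam_next
            if delta < 1e-14:
                break
    if np.any(rho_new <= 0):
        raise RuntimeError("constituent density became non-positive during G&R step")
    return rho_new, lam_new


def step_gnr(
    fields: PointFields,
    F: np.ndarray,
    sigma_h: np.ndarray,
    mix: MixtureParams,
    cfg: GnRStepConfig,
    *,
    active_scale: float = 1.0,
) -> PointFields:
    """One local G&R step for a batch of material points at frozen deformation.

    Elastin is untouched.  Points at homeostasis are exact fixed points.
    """
    Ff = np.einsum("nij,nfj->nfi", np.asarray(F, dtype=float), fields.f0)
    i4 = np.einsum("nfi,nfi->nf", Ff, Ff)
    sig, _, _ = fiber_stress_batch(F, fields, mix, active_scale=active_scale)
    sig_passive, _, _ = fiber_stress_batch(
        F, fields, mix, active_scale=0.0
    )
    active_sigma = sig[:, 0] - sig_passive[:, 0]
    rho_new, lam_new = step_gnr_batch(
        fields.rho0, fields.lambda_r, i4, active_sigma, sigma_h, mix, cfg
    )
    out = fields.copy()
    out.rho0 = rho_new
    out.lambda_r = lam_new
    return out
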