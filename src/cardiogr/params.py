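"""Material, geometric and turnover parameters of the myocardial mixture.

The myocardium is modeled as a constrained mixture of quasi-1D fiber
constituents (cardiomyocytes and four collagen fiber families) embedded in an
isotropic neo-Hookean ground matrix (mainly elastin).  All constituents occupy
every material point and deform together; each stores its own stress-free
configuration.

Units are SI throughout (Pa, kg, m); growth-and-remodeling time is measured in
days.  Pressures in configuration files are accepted in mmHg and converted at
the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

MMHG = 133.322387415  # Pa per mmHg


@dataclass(frozen=True)
class FiberConstituentParams:
    """Parameters of a quasi-1D fiber constituent (myocyte or collagen family).

    Attributes
    ----------
    a, b:
        Fung exponential stiffness (J/kg) and dimensionless exponent of the
        passive strain energy ``W = a/(2b) {exp[b (I4e-1)^2] - 1}``.
    lambda_h:
        Homeostatic elastic stretch, > 1.
    xi0:
        Initial mass fraction of this constituent in the mixture.
    k_gain:
        Growth gain factor (1/day) of the net mass production rate.
    T_survival:
        Mean survival time (day) of a deposited mass increment.
    sigma_act_max, lambda_0, lambda_max:
        Active-tone parameters (myocytes only): maximal active Cauchy stress
        (Pa) and the active stretches at zero and maximal active stress.
    """

    name: str
    a: float
    b: float
    lambda_h: float
    xi0: float
    k_gain: float
    T_survival: float
    sigma_act_max: float = 0.0
    lambda_0: float = 0.0
    lambda_max: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Fung parameters a, b must be positive")
        if self.lambda_h <= 1:
            raise ValueError("homeostatic stretch must exceed 1")
        if not 0 < self.xi0 < 1:
            raise ValueError("mass fraction must lie in (0, 1)")
        if self.T_survival <= 0:
            raise ValueError("mean survival time must be positive")
        if self.sigma_act_max and not self.lambda_0 < self.lambda_max:
            raise ValueError("active stretch bounds must satisfy lambda_0 < lambda_max")

    @property
    def is_active(self) -> bool:
        return self.sigma_act_max > 0


@dataclass(frozen=True)
class ElastinParams:
    """Neo-Hookean parameters of the non-remodeling ground-matrix constituent."""

    c1: float  # J/kg
    xi0: float

    def __post_init__(self) -> None:
        if self.c1 <= 0:
            raise ValueError("neo-Hookean coefficient must be positive")


@dataclass(frozen=True)
class MixtureParams:
    """Full parameter set of the myocardial constrained mixture.

    ``rho0_total`` is the total referential mass density at time 0; the
    volumetric penalty ``kappa`` ties det F to the referential mass ratio so
    that the spatial density stays (nearly) constant during growth.
    ``lambda_act0`` is the calibrated initial active stretch of the myocytes;
    it is stored explicitly and never recomputed implicitly.
    """

    rho0_total: float
    kappa: float
    elastin: ElastinParams
    myocyte: FiberConstituentParams
    collagen: tuple[FiberConstituentParams, ...]
    lambda_act0: float = 1.0
    #: stretch measure driving the active-tone evolution: "total" follows the
    #: total fiber stretch relative to the reference configuration; "elastic"
    #: follows the elastic stretch relative to the evolving natural
    #: configuration (active tone then re-adapts through turnover)
    active_reference: str = "total"

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.rho0_total <= 0:
            raise ValueError("kappa and rho0_total must be positive")
        xi = self.elastin.xi0 + self.myocyte.xi0 + sum(c.xi0 for c in self.collagen)
        if abs(xi - 1.0) > 1e-9:
            raise ValueError(f"mass fractions must sum to 1, got {xi}")
        if self.active_reference not in ("total", "elastic"):
            raise ValueError("active_reference must be 'total' or 'elastic'")

    @property
    def fibers(self) -> tuple[FiberConstituentParams, ...]:
        """Fiber constituents subject to growth and remodeling (myocyte first)."""
        return (self.myocyte, *self.collagen)

    @property
    def rho0_elastin(self) -> float:
        return self.elastin.xi0 * self.rho0_total

    def fiber_rho0(self) -> list[float]:
        return [f.xi0 * self.rho0_total for f in self.fibers]

    def with_gain_scale(self, gain_times_T: float) -> "MixtureParams":
        """Return a copy with all growth gains set to ``gain_times_T / T^i``."""
        myo = replace(self.myocyte, k_gain=gain_times_T / self.myocyte.T_survival)
        col = tuple(replace(c, k_gain=gain_times_T / c.T_survival) for c in self.collagen)
        return replace(self, myocyte=myo, collagen=col)


def passive_fiber_cauchy_stress(lambda_e: float, a: float, b: float, rho_hat: float) -> float:
    """Intensive passive fiber Cauchy stress ``2 rho_hat I4e dW/dI4e`` at elastic
    stretch ``lambda_e`` (tension only)."""
    i4e = lambda_e * lambda_e
    if i4e <= 1.0:
        return 0.0
    x = i4e - 1.0
    return 2.0 * rho_hat * i4e * a * x * math.exp(b * x * x)


def calibrate_active_stretch(
    myocyte: FiberConstituentParams, rho0_total: float, sigma_target: float
) -> float:
    """Initial active stretch such that the total (passive + active) myocyte
    fiber Cauchy stress at the homeostatic elastic stretch equals ``sigma_target``.

    The active stress factor is ``f = 1 - ((lambda_max - lambda_act)/(lambda_max
    - lambda_0))^2`` and the active stress carries the myocyte mass fraction
    (the active energy is normalized by the total mixture density); solving
    ``sigma_pas + xi0 sigma_act_max f = sigma_target`` for ``lambda_act``
    gives a closed form.
    """
    sigma_pas = passive_fiber_cauchy_stress(myocyte.lambda_h, myocyte.a, myocyte.b, rho0_total)
    f = (sigma_target - sigma_pas) / (myocyte.xi0 * myocyte.sigma_act_max)
    if not 0.0 <= f <= 1.0:
        raise ValueError("target stress not reachable by active-tone calibration")
    return myocyte.lambda_max - (myocyte.lambda_max - myocyte.lambda_0) * math.sqrt(1.0 - f)


#: Myocyte homeostatic fiber Cauchy stress installed as the set point (Pa).
SIGMA_H_MYOCYTE = 22.0e3


def human_lv_mixture(
    *,
    elastin_half_coefficient: bool = False,
    gain_times_T: float = 0.1,
    sigma_h_myocyte: float = SIGMA_H_MYOCYTE,
    active_reference: str = "total",
) -> MixtureParams:
    """Baseline parameter set of the human-LV study.

    Four collagen fiber families (fiber, cross-fiber, +/-45 deg) share the
    collagen mass fraction equally.  ``gain_times_T`` is the dimensionless
    growth constant ``k^i * T^i`` applied to every remodeling constituent.
    """
    rho0 = 1050.0  # kg/m^3
    myo = FiberConstituentParams(
        name="myocyte",
        a=7.6,
        b=11.4,
        lambda_h=1.1,
        xi0=0.6,
        k_gain=gain_times_T / 10.0,
        T_survival=10.0,
        sigma_act_max=54.0e3,
        lambda_0=0.8,
        lambda_max=1.4,
    )
    collagen = tuple(
        FiberConstituentParams(
            name=f"collagen_{tag}",
            a=568.0,
            b=11.2,
            lambda_h=1.062,
            xi0=0.1 / 4.0,
            k_gain=gain_times_T / 15.0,
            T_survival=15.0,
        )
        for tag in ("fiber", "cross", "diag_p", "diag_m")
    )
    elastin = ElastinParams(c1=72.0 / (2.0 if elastin_half_coefficient else 1.0), xi0=0.3)
    lam_act0 = calibrate_active_stretch(myo, rho0, sigma_h_myocyte)
    return MixtureParams(
        rho0_total=rho0,
        kappa=150.0e3,
        elastin=elastin,
        myocyte=myo,
        collagen=collagen,
        lambda_act0=lam_act0,
        active_reference=active_reference,
    )
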