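"""Desk-scale surrogates driving the identical constitutive/G&R kernels.

Two reduced models exercise the exact same code objects as the finite element
path (no duplicated formulas):

* a material-point driver applying stretch- or stress-controlled protocols to
  a single mixture point, and
* a thin-walled spherical LV surrogate whose wall is one mixture material
  point under equibiaxial in-plane stretch, in equilibrium with the cavity
  pressure through the Laplace relation ``sigma = p r / (2 h)``.

The surrogate exists for fast property studies (stability bifurcation,
reversal); it deliberately has no transmural gradients or helix architecture
and is not expected to reproduce the full 3D results quantitatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .constitutive import PointFields, fiber_stress_batch, mixture_pk_batch
from .gnr import GnRStepConfig, step_gnr
from .lv_model import homeostatic_stresses
from .params import MMHG, MixtureParams

__all__ = [
    "PointDriveProtocol",
    "drive_material_point",
    "ThinWallLV",
    "thin_wall_equilibrium",
    "run_reduced_gnr",
    "critical_pressure_reduced",
]


def planar_fiber_set() -> np.ndarray:
    """Fiber directions of a wall-plane material point: myocyte along x and
    collagen along x, y and +/-45 degrees, shape (1, 5, 3)."""
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    rt2 = math.sqrt(2.0)
    return np.stack([ex, ex, ey, (ex + ey) / rt2, (ex - ey) / rt2])[None]


def _cauchy_diag(F: np.ndarray, fields: PointFields, mix: MixtureParams) -> np.ndarray:
    """Diagonal mixture Cauchy stress components at a diagonal deformation."""
    P, _ = mixture_pk_batch(F, fields, mix, with_tangent=False)
    J = np.linalg.det(F[0])
    sig = P[0] @ F[0].T / J
    return np.array([sig[0, 0], sig[1, 1], sig[2, 2]])


@dataclass
class PointDriveProtocol:
    """Piecewise-constant control schedule for the material-point driver.

    ``schedule`` maps time (day) to the target value: the total fiber-axis
    stretch (stretch control) or the axial mixture Cauchy stress in Pa
    (stress control).  Targets hold from their time until the next entry.
    """

    control: str  # "stretch" | "stress"
    schedule: list[tuple[float, float]]
    duration: float
    dt: float | None = None
    scheme: str = "forward-euler"

    def __post_init__(self) -> None:
        if self.control not in ("stretch", "stress"):
            raise ValueError("control must be 'stretch' or 'stress'")
        if any(v <= 0 for _, v in self.schedule) and self.control == "stretch":
            raise ValueError("stretch targets must be positive")

    def target(self, s: float) -> float:
        v = self.schedule[0][1]
        for t, val in self.schedule:
            if s >= t:
                v = val
        return v


def drive_material_point(
    protocol: PointDriveProtocol,
    mix: MixtureParams,
    *,
    rho_bound: float = 5.0,
) -> pd.DataFrame:
    """Run a G&R protocol on one mixture material point.

    Stretch control prescribes ``F = diag(lam, lam^-1/2, lam^-1/2)`` per
    segment; stress control finds the axial and transverse stretches such that
    the axial mixture Cauchy stress matches the target with traction-free
    lateral faces.  Returns one row per G&R step with per-constituent fiber
    stresses, densities and remodeling stretches.  Densities exceeding
    ``rho_bound`` times their initial value terminate the run (runaway).
    """
    fields = PointFields.homeostatic(planar_fiber_set(), mix)
    sigma_h = homeostatic_stresses(mix)
    dt = protocol.dt or min(f.T_survival for f in mix.fibers) / 20.0
    cfg = GnRStepConfig(dt=dt, scheme=protocol.scheme)
    n_steps = int(round(protocol.duration / dt))
    rows = []
    x_guess = np.array([1.0, 1.0])
    rho_init = fields.rho0.sum()

    def F_of(lam: float, lam_t: float) -> np.ndarray:
        return np.diag([lam, lam_t, lam_t])[None]

    for k in range(n_steps + 1):
        s = k * dt
        tgt = protocol.target(s)
        if protocol.control == "stretch":
            F = F_of(tgt, 1.0 / math.sqrt(tgt))
        else:

            def res(x):
                sig = _cauchy_diag(F_of(*x), fields, mix)
                return [sig[0] - tgt, sig[1]]

            sol = optimize.root(res, x_guess, method="hybr")
            if not sol.success:
                raise RuntimeError("stress-control equilibrium failed")
            x_guess = sol.x
            F = F_of(*sol.x)
        sig, _, i4e = fiber_stress_batch(F, fields, mix)
        row = {"time": s, "mass_ratio": fields.rho0.sum() / rho_init}
        for c, p in enumerate(mix.fibers):
            row[f"sigma_{p.name}"] = sig[0, c]
            row[f"rho0_{p.name}"] = fields.rho0[0, c]
            row[f"lambda_r_{p.name}"] = fields.lambda_r[0, c]
        rows.append(row)
        if fields.rho0.sum() > rho_bound * rho_init:
            row["runaway"] = True
            break
        if k < n_steps:
            fields = step_gnr(fields, F, sigma_h, mix, cfg)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# thin-walled LV surrogate
# ---------------------------------------------------------------------------

@dataclass
class ThinWallLV:
    """Thin-walled spherical shell with a mixture wall material point.

    ``radius`` is the mid-wall cavity radius and ``thickness`` the wall
    thickness of the imaged reference state (m).  The in-plane directions of
    the wall material point follow :func:`planar_fiber_set`.
    """

    mix: MixtureParams
    radius: float = 24.5e-3
    thickness: float = 11.0e-3
    fields: PointFields = field(init=False)
    sigma_h: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.thickness > 0.5 * self.radius:
            import warnings

            warnings.warn("thin-wall assumption violated: thickness > radius/2")
        self.fields = PointFields.homeostatic(planar_fiber_set(), self.mix)
        self.sigma_h = homeostatic_stresses(self.mix)
        self.lambda_ref = np.array([1.0, 1.0])  # post-prestress reference stretches

    def equilibrium_residual(self, x: np.ndarray, p: float) -> list[float]:
        lam, lam_t = x
        F = np.diag([lam, lam, lam_t])[None]
        sig = _cauchy_diag(F, self.fields, self.mix)
        r = lam * self.radius
        h = lam_t * self.thickness
        laplace = p * r / (2.0 * h)
        return [0.5 * (sig[0] + sig[1]) - laplace, sig[2] + 0.5 * p]


def thin_wall_equilibrium(
    lv: ThinWallLV, p: float, x0: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the Laplace equilibrium at cavity pressure ``p`` (Pa).

    Returns ``(x, sigma)`` with ``x = (lam_inplane, lam_thickness)`` and the
    diagonal mixture Cauchy stress.  Raises if no equilibrium exists in the
    bracket (elastic instability).
    """
    if p < 0:
        raise ValueError("pressure must be non-negative")
    x0 = np.array([1.0, 1.0]) if x0 is None else x0
    sol = optimize.root(lambda x: lv.equilibrium_residual(x, p), x0, method="hybr")
    if not sol.success or np.any(sol.x <= 0):
        raise RuntimeError("no thin-wall equilibrium found (elastic instability)")
    lam, lam_t = sol.x
    sig = _cauchy_diag(np.diag([lam, lam, lam_t])[None], lv.fields, lv.mix)
    return sol.x, sig


def prestress_thin_wall(lv: ThinWallLV, p0: float) -> float:
    """Choose an isochoric in-plane elastin prestretch ``G = diag(g, g, g^-2)``
    so the equilibrium at the baseline pressure sits at (nearly) unit in-plane
    stretch, then store the resulting reference stretches."""

    def mismatch(g: float) -> float:
        lv.fields.G3D = np.diag([g, g, 1.0 / g**2])[None]
        x, _ = thin_wall_equilibrium(lv, p0)
        return x[0] - 1.0

    g = optimize.brentq(mismatch, 0.8, 1.25, xtol=1e-12)
    lv.fields.G3D = np.diag([g, g, 1.0 / g**2])[None]
    lv.lambda_ref, _ = thin_wall_equilibrium(lv, p0)
    return g


def run_reduced_gnr(
    lv: ThinWallLV,
    pressure_of: "callable",
    horizon: float,
    *,
    dt: float | None = None,
    scheme: str = "forward-euler",
    mass_bound: float = 5.0,
) -> pd.DataFrame:
    """Advance the thin-wall LV under a pressure schedule ``pressure_of(s)``
    (Pa), one quasi-static equilibrium + one local G&R step per time step."""
    mix = lv.mix
    dt = dt or min(f.T_survival for f in mix.fibers) / 20.0
    cfg = GnRStepConfig(dt=dt, scheme=scheme)
    n_steps = int(round(horizon / dt))
    x = lv.lambda_ref.copy()
    rho_init = lv.fields.rho0.sum() + lv.fields.rho0_elastin[0]
    rows = []
    for k in range(n_steps + 1):
        s = k * dt
        p = pressure_of(s)
        try:
            with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
                x, sig_mix = thin_wall_equilibrium(lv, p, x)
        except RuntimeError:
            rows.append({"time": s, "elastic_failure": True})
            break
        F = np.diag([x[0], x[0], x[1]])[None]
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            sig, _, _ = fiber_stress_batch(F, lv.fields, mix)
        dev = np.abs(sig[0] - lv.sigma_h) / lv.sigma_h
        mass_ratio = (lv.fields.rho0.sum() + lv.fields.rho0_elastin[0]) / rho_init
        coll = lv.fields.rho0[0, 1:].sum()
        row = {
            "time": s,
            "pressure": p / MMHG,
            "sigma_myocyte_mean": sig[0, 0],
            "thickness": x[1] / lv.lambda_ref[1] * lv.thickness,
            "diameter": 2.0 * x[0] / lv.lambda_ref[0] * lv.radius,
            "collagen_fraction_mean": coll
            / (lv.fields.rho0.sum() + lv.fields.rho0_elastin[0]),
            "mass_ratio": mass_ratio,
            "max_deviation": dev.max(),
        }
        for c, pc in enumerate(mix.fibers):
            row[f"dev_{pc.name}"] = dev[c]
        rows.append(row)
        if mass_ratio > mass_bound or not np.isfinite(dev).all():
            break
        if k < n_steps:
            with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
                lv.fields = step_gnr(lv.fields, F, lv.sigma_h, mix, cfg)
    return pd.DataFrame(rows)


def critical_pressure_reduced(
    mix: MixtureParams,
    *,
    p_low: float = 125.0,
    p_high: float = 400.0,
    tol: float = 2.5,
    horizon: float = 1500.0,
    eps_sigma: float = 1e-3,
    window: int = 10,
) -> float:
    """Bisect the smallest unstable pressure step (mmHg) of the thin-wall LV.

    ``p_low`` must be stable and ``p_high`` unstable under the classifier of
    the scenarios module; the returned boundary is accurate to ``tol`` mmHg.
    """
    from .scenarios import classify_stability

    def verdict(p_plus: float) -> str:
        lv = ThinWallLV(mix=mix)
        prestress_thin_wall(lv, 120.0 * MMHG)
        df = run_reduced_gnr(lv, lambda s: p_plus * MMHG, horizon)
        if "elastic_failure" in df.columns or df["mass_ratio"].iloc[-1] > 4.0:
            return "unstable"
        dev = df[[f"dev_{p.name}" for p in mix.fibers]].to_numpy()
        return classify_stability(dev, eps_sigma, window=window)[0]

    if verdict(p_low) != "stable":
        raise RuntimeError(f"lower bracket {p_low} mmHg is not stable")
    if verdict(p_high) == "stable":
        raise RuntimeError(f"upper bracket {p_high} mmHg is stable")
    lo, hi = p_low, p_high
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if verdict(mid) == "unstable":
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
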