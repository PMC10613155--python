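"""Recovery of the elastin prestretch field (prestressing).

The reference configuration is an imaged, loaded in-vivo state and is
therefore not stress-free.  The fibrillar constituents (myocytes, collagen)
are placed at their known homeostatic stretch via rank-one prestretch
tensors; the isotropic elastin matrix has no preferred state, so its
symmetric, isochoric prestretch tensor ``G3D`` is found iteratively such that
the loaded, prestretched body reproduces the reference geometry:

1. solve equilibrium at the target pressure (ramping loads and fiber
   prestretch linearly over the first ``ramp_steps`` iterations),
2. absorb the isochoric part of the resulting deformation into ``G3D`` via a
   polar decomposition (keeping ``G3D`` rotation-free),
3. repeat until the maximum nodal displacement norm falls below ``eps_pre``.

Boundary springs are prestressed consistently: their rest state is set to the
converged prestress displacement so they carry no force in the prestressed
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import NewtonReport
from .lv_model import LVModel, SolverConfig

__all__ = [
    "PrestressConfig",
    "PrestressReport",
    "fiber_prestretch_tensor",
    "update_elastin_prestretch",
    "run_prestress",
    "principal_prestretches",
]


@dataclass
class PrestressConfig:
    eps_pre: float = 1e-5  # displacement tolerance (m); 0.01 mm
    ramp_steps: int = 10
    max_iters: int = 500

    def __post_init__(self) -> None:
        if self.eps_pre <= 0 or self.ramp_steps < 1:
            raise ValueError("eps_pre must be positive and ramp_steps >= 1")


@dataclass
class PrestressReport:
    converged: bool
    iterations: int
    displacement_history: list[float] = field(default_factory=list)

    @property
    def final_displacement(self) -> float:
        return self.displacement_history[-1] if self.displacement_history else np.inf


def fiber_prestretch_tensor(lambda_h: float, f0: np.ndarray) -> np.ndarray:
    """Rank-one-plus-isotropic fiber prestretch ``G_i = lambda_h f0 f0^T +
    lambda_h^{-1/2}(I - f0 f0^T)``; unit determinant by construction."""
    if lambda_h <= 0:
        raise ValueError("homeostatic stretch must be positive")
    f0 = np.asarray(f0, dtype=float)
    M = np.outer(f0, f0)
    return lambda_h * M + (np.eye(3) - M) / np.sqrt(lambda_h)


def _polar_symmetric_batch(Fp: np.ndarray) -> np.ndarray:
    """Symmetric (right) factor of the polar decomposition, renormalized to
    unit determinant against roundoff."""
    _, S, Vt = np.linalg.svd(Fp)
    G = np.einsum("nai,na,nak->nik", Vt, S, Vt)
    G /= np.linalg.det(G)[:, None, None] ** (1.0 / 3.0)
    return G


def update_elastin_prestretch(G_k: np.ndarray, F: np.ndarray) -> np.ndarray:
    """One prestretch update: the rotation-free factor of ``Fbar G_k`` with
    ``Fbar`` the isochoric part of ``F``."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if J <= 0:
        raise ValueError("deformation gradient must be invertible with det > 0")
    Fbar = F / J ** (1.0 / 3.0)
    return _polar_symmetric_batch((Fbar @ G_k)[None])[0]


def run_prestress(
    model: LVModel,
    p: float,
    cfg: PrestressConfig | None = None,
    *,
    solver_cfg: SolverConfig | None = None,
) -> PrestressReport:
    """Iterate the elastin prestretch until the loaded configuration matches
    the reference configuration within ``eps_pre`` (updates ``model.fields.G3D``
    and the spring rest state in place)."""
    cfg = cfg or PrestressConfig()
    u = np.zeros(model.disc.n_dofs)
    hist: list[float] = []
    converged = False
    it = 0
    while it < cfg.max_iters:
        it += 1
        g = min(1.0, it / cfg.ramp_steps)
        model.set_prestretch_scale(g)
        u, rep = model.solve(g * p, u0=u, active_scale=g, cfg=solver_cfg)
        if not rep.converged:
            break
        d = float(np.linalg.norm(u.reshape(-1, 3), axis=1).max())
        hist.append(d)
        if g >= 1.0 and d < cfg.eps_pre:
            converged = True
            break
        F = model.disc.deformation_gradients(u)
        J = np.linalg.det(F)
        Fbar = F / J[:, None, None] ** (1.0 / 3.0)
        model.fields.G3D = _polar_symmetric_batch(Fbar @ model.fields.G3D)
        # prestress the boundary springs: keep their current force at the new
        # zero-displacement state so they carry the load reaction at u = 0
        model.spring_rest = model.spring_rest - u
        u = np.zeros_like(u)
    model.prestress_displacement = u.copy()
    return PrestressReport(converged, it, hist)


def principal_prestretches(G3D: np.ndarray) -> np.ndarray:
    """Sorted (descending) principal stretches of the elastin prestretch
    tensors, shape (n, 3)."""
    return np.linalg.eigvalsh(G3D)[:, ::-1]
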