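"""Idealized left ventricle: geometry, fiber architecture, and the
quasi-static nonlinear finite element problem.

The virtual-work statement combines the mixture stress over the wall,
omnidirectional springs on the base (left atrium support), reference-normal
springs on the epicardium (pericardium and surrounding tissue), and the
follower systolic pressure on the endocardium.

The myocyte helix angle varies linearly in the normalized transmural
coordinate from ``phi_endo`` (+60 deg) at the endocardium to ``phi_epi``
(-60 deg) at the epicardium; the transmural coordinate comes directly from
the analytic ellipsoidal parametrization of the mesh generator.  Four
collagen fiber families lie in the local wall plane along the myocyte,
cross-fiber and +/-45 deg directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .constitutive import PointFields, fiber_stress_batch, mixture_pk_batch
from .fem import Discretization, NewtonConfig, NewtonReport, SurfaceTerm, newton_solve
from .mesh import LVGeometry, TetMesh, make_truncated_prolate_spheroid
from .params import MixtureParams

__all__ = ["SolverConfig", "LVModel", "assign_fiber_field", "homeostatic_stresses"]


def homeostatic_stresses(mix: MixtureParams) -> np.ndarray:
    """Per-constituent homeostatic fiber Cauchy stress (Pa), evaluated from the
    constitutive relation at the homeostatic elastic stretch (myocyte active
    tone at the calibrated initial active stretch)."""
    from .constitutive import active_fiber_stress, fung_fiber_energy_and_derivative

    out = []
    for p in mix.fibers:
        i4e = p.lambda_h**2
        _, dW = fung_fiber_energy_and_derivative(i4e, p)
        s = 2.0 * mix.rho0_total * i4e * dW
        if p.is_active:
            s += active_fiber_stress(mix.lambda_act0, p.xi0, p)
        out.append(s)
    return np.array(out)


def assign_fiber_field(
    disc: Discretization,
    node_t: np.ndarray,
    phi_endo: float = 60.0,
    phi_epi: float = -60.0,
    *,
    apex_cutoff: float = 1e-3,
) -> np.ndarray:
    """Gauss-point fiber frames, shape ``(n_gp, 5, 3)``.

    Order: myocyte, collagen-fiber, collagen-cross, collagen +45, collagen
    -45.  The local wall plane is spanned by the circumferential direction
    (projected perpendicular to the transmural gradient) and its in-plane
    complement.  Near the apex the circumferential direction degenerates; such
    points copy it from the nearest well-defined Gauss point (``apex_cutoff``
    is relative to the maximal in-plane radius).
    """
    t = np.clip(disc.interpolate(node_t), 0.0, 1.0)
    X = disc.gp_x
    n = disc.gradient_operator(node_t)
    n /= np.linalg.norm(n, axis=1, keepdims=True)

    zhat = np.array([0.0, 0.0, 1.0])
    c = np.cross(np.broadcast_to(zhat, X.shape), X)
    cn = np.linalg.norm(c, axis=1)
    r_max = np.linalg.norm(X[:, :2], axis=1).max()
    good = cn > apex_cutoff * r_max
    if not np.all(good):
        bad = np.where(~good)[0]
        gi = np.where(good)[0]
        for b in bad:
            j = gi[np.argmin(np.linalg.norm(X[gi] - X[b], axis=1))]
            c[b] = c[j]
            cn[b] = np.linalg.norm(c[b])
    c /= cn[:, None]

    e1 = c - np.einsum("ni,ni->n", c, n)[:, None] * n
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(n, e1)

    alpha = np.radians(phi_endo + (phi_epi - phi_endo) * t)
    ca, sa = np.cos(alpha)[:, None], np.sin(alpha)[:, None]
    m = ca * e1 + sa * e2
    s = -sa * e1 + ca * e2
    rt2 = math.sqrt(2.0)
    return np.stack([m, m, s, (m + s) / rt2, (m - s) / rt2], axis=1)


@dataclass
class SolverConfig:
    """Newton settings for the quasi-static solves (artifact plumbing)."""

    rtol: float = 1e-8  # residual tolerance relative to the external load scale
    atol_floor: float = 1e-10  # absolute floor (N)
    max_iter: int = 30
    max_backtracks: int = 12


@dataclass
class LVModel:
    """Assembled mixture body: mesh + fibers + boundary conditions + state.

    Also used for generic fixtures (box, spherical shells): any tagged facet
    set can carry springs, a follower pressure or Dirichlet constraints.
    """

    mesh: TetMesh
    mix: MixtureParams
    disc: Discretization = field(init=False)
    fields: PointFields = field(init=False)
    sigma_h: np.ndarray = field(init=False)
    pressure_tag: str = "endo"
    c_base: float = 2.0e6  # Pa/m  (= 2.0 kPa/mm)
    c_p: float = 0.2e6  # Pa/m
    phi_endo: float = 60.0
    phi_epi: float = -60.0
    fixed_dofs: np.ndarray | None = None  # boolean (n_dofs,) of constrained dofs

    def __post_init__(self) -> None:
        self.disc = Discretization(self.mesh)
        self.surfaces = {
            tag: SurfaceTerm(self.mesh, f) for tag, f in self.mesh.facets.items()
        }
        if self.mesh.node_t is not None and not np.any(np.isnan(self.mesh.node_t)):
            f0 = assign_fiber_field(
                self.disc, self.mesh.node_t, self.phi_endo, self.phi_epi
            )
        else:  # fixtures: fibers along x, wall plane (x, y)
            ngp = self.disc.gp_x.shape[0]
            ex, ey = np.array([1.0, 0, 0]), np.array([0.0, 1, 0])
            d1 = (ex + ey) / math.sqrt(2.0)
            d2 = (ex - ey) / math.sqrt(2.0)
            f0 = np.tile(np.stack([ex, ex, ey, d1, d2]), (ngp, 1, 1))
        self.fields = PointFields.homeostatic(f0, self.mix)
        self.sigma_h = homeostatic_stresses(self.mix)
        self._K_spring: sp.csr_matrix | None = None
        self.spring_rest = np.zeros(self.disc.n_dofs)
        self._build_springs()
        self.free = np.ones(self.disc.n_dofs, dtype=bool)
        if self.fixed_dofs is not None:
            self.free &= ~self.fixed_dofs

    # -- construction -------------------------------------------------------

    @classmethod
    def from_geometry(
        cls,
        geom: LVGeometry,
        mix: MixtureParams,
        *,
        target_elements: int = 4000,
        order: int = 2,
        c_base: float = 2.0e6,
        c_p: float = 0.2e6,
        phi_endo: float = 60.0,
        phi_epi: float = -60.0,
    ) -> "LVModel":
        mesh = make_truncated_prolate_spheroid(geom, target_elements, order=order)
        return cls(
            mesh=mesh,
            mix=mix,
            c_base=c_base,
            c_p=c_p,
            phi_endo=phi_endo,
            phi_epi=phi_epi,
        )

    def _build_springs(self) -> None:
        K = sp.csr_matrix((self.disc.n_dofs, self.disc.n_dofs))
        if "base" in self.surfaces and self.c_base > 0:
            K = K + self.surfaces["base"].spring_matrix_omni(self.c_base)
        if "epi" in self.surfaces and self.c_p > 0:
            K = K + self.surfaces["epi"].spring_matrix_normal(self.c_p)
        self._K_spring = K

    # -- state handling -----------------------------------------------------

    def set_prestretch_scale(self, scale: float) -> None:
        """Ramp the homeostatic fiber prestretch: lambda_r = 1/(1 + scale
        (lambda_h - 1)) at every Gauss point (used during prestressing)."""
        lam_h = np.array(
            [1.0 + scale * (f.lambda_h - 1.0) for f in self.mix.fibers]
        )
        self.fields.lambda_r[:] = 1.0 / lam_h

    # -- assembly and solution ----------------------------------------------

    def assemble(
        self,
        u: np.ndarray,
        p: float,
        *,
        active_scale: float = 1.0,
        need_tangent: bool = True,
    ) -> tuple[np.ndarray, sp.csr_matrix | None]:
        """Residual of the virtual-work statement and its consistent tangent."""
        F = self.disc.deformation_gradients(u)
        if np.any(np.linalg.det(F) <= 0):
            return np.full(self.disc.n_dofs, np.nan), self._K_spring
        P, A = mixture_pk_batch(
            F, self.fields, self.mix, active_scale=active_scale, with_tangent=need_tangent
        )
        R = self.disc.internal_force(P)
        K = self.disc.stiffness(A) if need_tangent else None
        if self._K_spring is not None and self._K_spring.nnz:
            R = R + self._K_spring @ (u - self.spring_rest)
            if need_tangent:
                K = K + self._K_spring
        if p != 0.0 and self.pressure_tag in self.surfaces:
            x_cur = (self.mesh.nodes.ravel() + u).reshape(-1, 3)
            fp, Kp = self.surfaces[self.pressure_tag].follower_pressure(
                x_cur, p, with_tangent=need_tangent
            )
            R = R + fp
            if need_tangent:
                K = K + Kp
        return R, K

    def load_scale(self, p: float) -> float:
        """Characteristic external force (N) used to scale Newton tolerances."""
        area = (
            self.surfaces[self.pressure_tag].area()
            if self.pressure_tag in self.surfaces
            else 1.0
        )
        stress_scale = max(abs(p), 1e3)
        return stress_scale * area

    def solve(
        self,
        p: float,
        u0: np.ndarray | None = None,
        *,
        active_scale: float = 1.0,
        cfg: SolverConfig | None = None,
    ) -> tuple[np.ndarray, NewtonReport]:
        """Solve quasi-static equilibrium at pressure ``p`` (Pa)."""
        cfg = cfg or SolverConfig()
        u0 = np.zeros(self.disc.n_dofs) if u0 is None else u0
        ncfg = NewtonConfig(
            tol=max(cfg.atol_floor, cfg.rtol * self.load_scale(p)),
            max_iter=cfg.max_iter,
            max_backtracks=cfg.max_backtracks,
        )
        return newton_solve(
            lambda u, tang: self.assemble(
                u, p, active_scale=active_scale, need_tangent=tang
            ),
            u0,
            self.free,
            ncfg,
        )

    # -- derived quantities --------------------------------------------------

    def constituent_stresses(
        self, u: np.ndarray, *, active_scale: float = 1.0
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(sigma, dsigma_dI4e, I4e) per Gauss point and fiber constituent."""
        F = self.disc.deformation_gradients(u)
        return fiber_stress_batch(F, self.fields, self.mix, active_scale=active_scale)

    def deviation_from_homeostasis(self, u: np.ndarray) -> np.ndarray:
        """Max over Gauss points of |sigma - sigma_h|/sigma_h per constituent."""
        sig, _, _ = self.constituent_stresses(u)
        return np.max(np.abs(sig - self.sigma_h) / self.sigma_h, axis=0)

    def deformed_nodes(self, u: np.ndarray) -> np.ndarray:
        return self.mesh.nodes + u.reshape(-1, 3)
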