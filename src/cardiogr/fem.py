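"""Total-Lagrangian finite elements on tetrahedral meshes.

Linear (P1, 1-point rule) and quadratic (P2, 4-point rule) tetrahedra with
vectorized assembly of the internal virtual-work residual and its consistent
tangent; boundary surface machinery for omnidirectional and normal-direction
springs and for the deformation-dependent (follower) pressure load of the
endocardium; and a damped Newton solver with backtracking line search.

The residual convention follows the virtual-work statement
``R(u) = f_int(u) + f_springs(u) + f_pressure(u) = 0`` with the pressure term
``+ p J F^{-T} N_0`` integrated over the reference endocardial surface
(outward-of-solid normals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TetMesh

__all__ = [
    "Discretization",
    "SurfaceTerm",
    "NewtonConfig",
    "NewtonReport",
    "newton_solve",
]

_EPS_LC = np.zeros((3, 3, 3))
for _i, _j, _k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
    _EPS_LC[_i, _j, _k] = 1.0
    _EPS_LC[_i, _k, _j] = -1.0


# ---------------------------------------------------------------------------
# reference elements
# ---------------------------------------------------------------------------

def _tet_shape(order: int, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape values (nq, nen) and reference gradients (nq, nen, 3)."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    l0 = 1.0 - x - y - z
    if order == 1:
        N = np.stack([l0, x, y, z], axis=1)
        dN = np.tile(
            np.array([[-1.0, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]]), (len(pts), 1, 1)
        )
        return N, dN
    lam = np.stack([l0, x, y, z], axis=1)  # (nq, 4)
    dlam = np.array([[-1.0, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]])  # (4, 3)
    N = np.empty((len(pts), 10))
    dN = np.empty((len(pts), 10, 3))
    for a in range(4):
        N[:, a] = lam[:, a] * (2.0 * lam[:, a] - 1.0)
        dN[:, a] = (4.0 * lam[:, a] - 1.0)[:, None] * dlam[a]
    edges = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))
    for e, (i, j) in enumerate(edges):
        N[:, 4 + e] = 4.0 * lam[:, i] * lam[:, j]
        dN[:, 4 + e] = 4.0 * (lam[:, i][:, None] * dlam[j] + lam[:, j][:, None] * dlam[i])
    return N, dN


def _tet_quadrature(order: int) -> tuple[np.ndarray, np.ndarray]:
    if order == 1:
        return np.array([[0.25, 0.25, 0.25]]), np.array([1.0 / 6.0])
    a, b = 0.5854101966249685, 0.1381966011250105
    pts = np.array([[b, b, b], [a, b, b], [b, a, b], [b, b, a]])
    return pts, np.full(4, 1.0 / 24.0)


def _tri_shape(order: int, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x, y = pts[:, 0], pts[:, 1]
    l0 = 1.0 - x - y
    if order == 1:
        N = np.stack([l0, x, y], axis=1)
        dN = np.tile(np.array([[-1.0, -1], [1, 0], [0, 1]]), (len(pts), 1, 1))
        return N, dN
    lam = np.stack([l0, x, y], axis=1)
    dlam = np.array([[-1.0, -1], [1, 0], [0, 1]])
    N = np.empty((len(pts), 6))
    dN = np.empty((len(pts), 6, 2))
    for a in range(3):
        N[:, a] = lam[:, a] * (2.0 * lam[:, a] - 1.0)
        dN[:, a] = (4.0 * lam[:, a] - 1.0)[:, None] * dlam[a]
    edges = ((0, 1), (1, 2), (0, 2))
    for e, (i, j) in enumerate(edges):
        N[:, 3 + e] = 4.0 * lam[:, i] * lam[:, j]
        dN[:, 3 + e] = 4.0 * (lam[:, i][:, None] * dlam[j] + lam[:, j][:, None] * dlam[i])
    return N, dN


def _tri_quadrature(order: int) -> tuple[np.ndarray, np.ndarray]:
    if order == 1:
        return np.array([[1.0 / 3.0, 1.0 / 3.0]]), np.array([0.5])
    pts = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
    return pts, np.full(3, 1.0 / 6.0)


# ---------------------------------------------------------------------------
# volume discretization
# ---------------------------------------------------------------------------

class Discretization:
    """Precomputed quadrature data and scatter indices for one tet mesh."""

    def __init__(self, mesh: TetMesh):
        self.mesh = mesh
        self.order = mesh.order
        qp, qw = _tet_quadrature(self.order)
        N, dNr = _tet_shape(self.order, qp)
        self.N = N  # (nq, nen)
        xe = mesh.nodes[mesh.elems]  # (Ne, nen, 3)
        # Jacobian per element/GP: J_ij = sum_a x_a,i dN_a/dxi_j
        J = np.einsum("eai,qaj->eqij", xe, dNr)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise ValueError("non-positive element Jacobian")
        Jinv = np.linalg.inv(J)
        self.dNdX = np.einsum("qaj,eqji->eqai", dNr, Jinv)  # (Ne, nq, nen, 3)
        self.w = detJ * qw[None, :]  # (Ne, nq)
        self.n_gp = self.w.size
        self.gp_x = np.einsum("qa,eai->eqi", N, xe).reshape(-1, 3)
        ne, nen = mesh.elems.shape
        dofs = (3 * mesh.elems[:, :, None] + np.arange(3)).reshape(ne, 3 * nen)
        self._rows = np.repeat(dofs, 3 * nen, axis=1).ravel()
        self._cols = np.tile(dofs, (1, 3 * nen)).ravel()
        self._dofs = dofs
        self.n_dofs = 3 * mesh.n_nodes
        # B-operator mapping element dof (b, k) to (k, L) = dN_b/dX_L delta_kk'
        nq = self.w.shape[1]
        T = np.zeros((ne, nq, 3, 3, nen, 3))
        for k in range(3):
            T[:, :, k, :, :, k] = self.dNdX.transpose(0, 1, 3, 2)
        self._B = np.ascontiguousarray(T.reshape(ne * nq, 9, 3 * nen))

    def interpolate(self, nodal: np.ndarray) -> np.ndarray:
        """Interpolate a nodal scalar to all Gauss points (flattened)."""
        return np.einsum("qa,ea->eq", self.N, nodal[self.mesh.elems]).ravel()

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        """F = I + grad u at every Gauss point, shape (n_gp, 3, 3)."""
        ue = u.reshape(-1, 3)[self.mesh.elems]  # (Ne, nen, 3)
        grad = np.einsum("eai,eqaj->eqij", ue, self.dNdX)
        F = grad.reshape(-1, 3, 3)
        F[:, 0, 0] += 1.0
        F[:, 1, 1] += 1.0
        F[:, 2, 2] += 1.0
        return F

    def gradient_operator(self, nodal_scalar: np.ndarray) -> np.ndarray:
        """Spatial gradient of a nodal scalar at every Gauss point."""
        se = nodal_scalar[self.mesh.elems]
        return np.einsum("ea,eqai->eqi", se, self.dNdX).reshape(-1, 3)

    def internal_force(self, P: np.ndarray) -> np.ndarray:
        """Assemble the internal force from first PK stresses at Gauss points."""
        ne, nq = self.w.shape
        Pe = P.reshape(ne, nq, 3, 3)
        fe = np.einsum("eq,eqij,eqaj->eai", self.w, Pe, self.dNdX, optimize=True)
        return np.bincount(
            self._dofs.ravel(), weights=fe.reshape(ne, -1).ravel(), minlength=self.n_dofs
        )

    def stiffness(self, A: np.ndarray) -> sp.csr_matrix:
        """Assemble the tangent from material tangents dP/dF at Gauss points."""
        ne, nq = self.w.shape
        Aw = (A.reshape(ne * nq, 9, 9)) * self.w.reshape(-1, 1, 1)
        AB = Aw @ self._B  # (nq_tot, 9, 3 nen)
        Ke = (self._B.transpose(0, 2, 1) @ AB).reshape(ne, nq, 3 * self.mesh.elems.shape[1], -1)
        data = Ke.sum(axis=1).ravel()
        K = sp.coo_matrix(
            (data, (self._rows, self._cols)), shape=(self.n_dofs, self.n_dofs)
        )
        return K.tocsr()

    def volume(self) -> float:
        return float(self.w.sum())

    def integrate_gp(self, gp_values: np.ndarray) -> float:
        """Integrate a Gauss-point scalar field over the reference volume."""
        return float((gp_values.reshape(self.w.shape) * self.w).sum())


# ---------------------------------------------------------------------------
# boundary surfaces
# ---------------------------------------------------------------------------

@dataclass
class SurfaceTerm:
    """Quadrature data over one tagged boundary facet set.

    Provides spring matrices (assembled once) and the follower-pressure
    residual and tangent (recomputed from the current nodal positions).
    """

    mesh: TetMesh
    facets: np.ndarray  # (Nf, 3|6)
    N: np.ndarray = field(init=False)
    dN: np.ndarray = field(init=False)
    w_ref: np.ndarray = field(init=False)  # reference area weights (Nf, nq)
    N0: np.ndarray = field(init=False)  # unit reference normals (Nf, nq, 3)

    def __post_init__(self) -> None:
        order = 1 if self.facets.shape[1] == 3 else 2
        qp, qw = _tri_quadrature(order)
        self.N, self.dN = _tri_shape(order, qp)
        xf = self.mesh.nodes[self.facets]  # (Nf, nfn, 3)
        g = np.einsum("fai,qaj->fqij", xf, self.dN)  # (Nf, nq, 3, 2)
        cr = np.cross(g[..., 0], g[..., 1])
        area = np.linalg.norm(cr, axis=-1)
        self.N0 = cr / area[..., None]
        self.w_ref = area * qw[None, :]
        nf, nfn = self.facets.shape
        dofs = (3 * self.facets[:, :, None] + np.arange(3)).reshape(nf, 3 * nfn)
        self._dofs = dofs
        self._rows = np.repeat(dofs, 3 * nfn, axis=1).ravel()
        self._cols = np.tile(dofs, (1, 3 * nfn)).ravel()
        self.n_dofs = 3 * self.mesh.n_nodes

    def area(self) -> float:
        return float(self.w_ref.sum())

    def _scatter_matrix(self, Kf: np.ndarray) -> sp.csr_matrix:
        nf, nfn = self.facets.shape
        data = Kf.reshape(nf, 3 * nfn, 3 * nfn).ravel()
        return sp.coo_matrix(
            (data, (self._rows, self._cols)), shape=(self.n_dofs, self.n_dofs)
        ).tocsr()

    def spring_matrix_omni(self, stiffness: float) -> sp.csr_matrix:
        """Omnidirectional spring bed: K = c * int N_a N_b dGamma * I3."""
        Ms = np.einsum("fq,qa,qb->fab", self.w_ref, self.N, self.N)
        Kf = stiffness * np.einsum("fab,ik->faibk", Ms, np.eye(3))
        return self._scatter_matrix(Kf)

    def spring_matrix_normal(self, stiffness: float) -> sp.csr_matrix:
        """Reference-normal spring bed: K = c * int N_a N_b N0 x N0 dGamma."""
        Kf = stiffness * np.einsum(
            "fq,qa,qb,fqi,fqk->faibk", self.w_ref, self.N, self.N, self.N0, self.N0
        )
        return self._scatter_matrix(Kf)

    def follower_pressure(
        self, x_current: np.ndarray, p: float, *, with_tangent: bool = True
    ) -> tuple[np.ndarray, sp.csr_matrix | None]:
        """Residual (+ tangent) of the follower pressure term
        ``+ p J F^{-T} N0`` over this surface (deformed-normal load)."""
        qw = _tri_quadrature(1 if self.facets.shape[1] == 3 else 2)[1]
        xf = x_current[self.facets]  # (Nf, nfn, 3)
        g = np.einsum("fai,qaj->fqij", xf, self.dN)
        g1, g2 = g[..., 0], g[..., 1]
        cr = np.cross(g1, g2)  # deformed-normal area vector per unit ref-param
        f = np.zeros(self.n_dofs)
        fe = p * np.einsum("q,qa,fqi->fai", qw, self.N, cr)
        np.add.at(f, self._dofs, fe.reshape(self.facets.shape[0], -1))
        if not with_tangent:
            return f, None
        # d(g1 x g2)_i / dx_bk = dNb1 eps_ikm g2_m + dNb2 eps_ijk g1_j
        t1 = np.einsum("qb,ikm,fqm->fqbik", self.dN[..., 0], _EPS_LC, g2)
        t2 = np.einsum("qb,ijk,fqj->fqbik", self.dN[..., 1], _EPS_LC, g1)
        Kf = p * np.einsum("q,qa,fqbik->faibk", qw, self.N, t1 + t2)
        return f, self._scatter_matrix(Kf)

    def enclosed_volume(self, x_current: np.ndarray, cap_ring: np.ndarray | None = None) -> float:
        """Volume enclosed by this (open) surface after closing it with a fan
        over its own boundary loop, via the divergence theorem.

        Quadratic facets are subdivided into their four corner/mid-node
        triangles.  The cap fan is wound opposite to the boundary edges so the
        closed triangulation is consistently oriented (translation invariant).
        ``cap_ring`` is accepted for backward compatibility and ignored.
        """
        tris: list[tuple[int, int, int]] = []
        if self.facets.shape[1] == 6:
            for f in self.facets:
                tris += [
                    (f[0], f[3], f[5]),
                    (f[3], f[1], f[4]),
                    (f[5], f[4], f[2]),
                    (f[3], f[4], f[5]),
                ]
        else:
            tris = [tuple(f) for f in self.facets]
        directed = set()
        for a, b, c in tris:
            directed.update(((a, b), (b, c), (c, a)))
        boundary = [(a, b) for (a, b) in directed if (b, a) not in directed]
        x = x_current
        v = 0.0
        for a, b, c in tris:
            v += np.dot(x[a], np.cross(x[b], x[c]))
        if boundary:
            nodes = {a for a, _ in boundary} | {b for _, b in boundary}
            centroid = x[list(nodes)].mean(axis=0)
            for a, b in boundary:  # cap edge (b, a) closes the directed edge
                v += np.dot(centroid, np.cross(x[b], x[a]))
        return abs(v) / 6.0


# ---------------------------------------------------------------------------
# Newton solver
# ---------------------------------------------------------------------------

@dataclass
class NewtonConfig:
    tol: float = 1e-8  # absolute residual norm (N), scaled by caller
    max_iter: int = 30
    max_backtracks: int = 12
    min_step: float = 1e-6


@dataclass
class NewtonReport:
    converged: bool
    iterations: int
    residual_norms: list[float]

    @property
    def final_residual(self) -> float:
        return self.residual_norms[-1] if self.residual_norms else np.inf


def newton_solve(
    assemble,
    u0: np.ndarray,
    free: np.ndarray,
    cfg: NewtonConfig,
) -> tuple[np.ndarray, NewtonReport]:
    """Damped Newton iteration for ``R(u) = 0`` on the free dofs.

    ``assemble(u, need_tangent)`` returns ``(R, K)``; ``free`` is a boolean
    dof mask.  Backtracking halves the step until the residual norm decreases.
    """
    u = u0.copy()
    R, K = assemble(u, True)
    norms = [float(np.linalg.norm(R[free]))]
    for it in range(cfg.max_iter):
        if norms[-1] < cfg.tol:
            return u, NewtonReport(True, it, norms)
        Kff = K[free][:, free].tocsc()
        try:  # MMD on A + A^T: fast for the nearly-symmetric FEM pattern
            du = spla.splu(Kff, permc_spec="MMD_AT_PLUS_A").solve(-R[free])
        except RuntimeError:  # singular factor: report non-convergence
            return u, NewtonReport(False, it, norms)
        if not np.all(np.isfinite(du)):
            return u, NewtonReport(False, it, norms)
        alpha = 1.0
        accepted = False
        while not accepted:
            u_try = u.copy()
            u_try[free] += alpha * du
            R_try, _ = assemble(u_try, False)
            n_try = float(np.linalg.norm(R_try[free]))
            if np.isfinite(n_try) and (n_try < norms[-1] or n_try < cfg.tol):
                u = u_try
                norms.append(n_try)
                accepted = True
            else:
                alpha *= 0.5
                if alpha < cfg.min_step:
                    norms.append(n_try)
                    return u, NewtonReport(False, it + 1, norms)
        if norms[-1] < cfg.tol:
            return u, NewtonReport(True, it + 1, norms)
        R, K = assemble(u, True)
    converged = norms[-1] < cfg.tol
    return u, NewtonReport(converged, cfg.max_iter, norms)
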