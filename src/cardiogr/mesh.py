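"""Tetrahedral meshing of the idealized left ventricle.

The LV wall is the volume between two coaxial truncated prolate spheroids
(endocardial and epicardial surfaces) cut by a base plane normal to the long
axis.  A structured parametric grid (transmural x meridional x circumferential)
is triangulated with the Kuhn/Freudenthal 6-tet split, which is face-conforming
across the periodic seam; cells collapsed at the apex pole are dropped.
Quadratic (10-node) elements place their mid-edge nodes through the exact
geometry map, so the curved surfaces are resolved to high order.

The long axis is z; the apex sits at ``z = -a`` and the base plane at
``z = +c_trunc`` above the equator (z = 0).  The meridional grid contains the
equatorial ring of both surfaces exactly, which the mid-cavity metrics use.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["LVGeometry", "TetMesh", "make_truncated_prolate_spheroid", "box_mesh"]


@dataclass(frozen=True)
class LVGeometry:
    """Semi-axes (m) of the two ellipsoidal surfaces and the truncation height.

    ``a`` are the major (long-axis) and ``b`` the minor (equatorial) radii;
    the wall is truncated at ``z = c_trunc`` above the equator.
    """

    a_epi: float = 55e-3
    b_epi: float = 30e-3
    a_endo: float = 46e-3
    b_endo: float = 19e-3
    c_trunc: float = 13e-3

    def __post_init__(self) -> None:
        if not (self.a_epi > self.a_endo and self.b_epi > self.b_endo):
            raise ValueError("epicardial radii must exceed endocardial radii")
        if not 0 <= self.c_trunc < self.a_endo:
            raise ValueError("truncation height must lie within the endocardial axis")

    def theta_base(self, a: float) -> float:
        """Polar angle (from the apex) at which an ellipsoid with long semi-axis
        ``a`` meets the base plane ``z = c_trunc``."""
        return math.acos(-self.c_trunc / a)


# VTK-ordered edges of the 10-node tetrahedron
_TET_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))


@dataclass
class TetMesh:
    """A (possibly curved) tetrahedral mesh with tagged boundary facets.

    ``elems`` holds 4 or 10 node ids per element (VTK ordering); ``facets``
    maps surface tags to arrays of 3- or 6-node triangles oriented outward.
    ``node_t`` is the normalized transmural coordinate (0 endocardium,
    1 epicardium) where defined, NaN otherwise (box fixtures).
    """

    nodes: np.ndarray
    elems: np.ndarray
    order: int
    facets: dict[str, np.ndarray] = field(default_factory=dict)
    node_t: np.ndarray | None = None
    rings: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elems.shape[0]

    def corner_volume(self) -> float:
        """Total volume of the straight-sided (corner-node) tetrahedra."""
        x = self.nodes[self.elems[:, :4]]
        v = np.einsum(
            "ei,ei->e",
            x[:, 1] - x[:, 0],
            np.cross(x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]),
        )
        return float(np.abs(v).sum() / 6.0)

    def statistics(self) -> dict[str, float]:
        return {
            "n_nodes": float(self.n_nodes),
            "n_elements": float(self.n_elements),
            "order": float(self.order),
            "corner_volume": self.corner_volume(),
        }


def _kuhn_tets(c: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Six-tet Kuhn split of one hexahedron given its 2x2x2 corner ids."""
    tets = []
    for perm in itertools.permutations(range(3)):
        idx = np.zeros(3, dtype=int)
        verts = [c[tuple(idx)]]
        for ax in perm:
            idx[ax] = 1
            verts.append(c[tuple(idx)])
        if len(set(verts)) == 4:
            tets.append(tuple(verts))
    return tets


def _orient_positive(nodes: np.ndarray, elems: np.ndarray) -> np.ndarray:
    x = nodes[elems[:, :4]]
    v = np.einsum(
        "ei,ei->e", x[:, 1] - x[:, 0], np.cross(x[:, 2] - x[:, 0], x[:, 3] - x[:, 0])
    )
    flip = v < 0
    elems = elems.copy()
    elems[flip, 2], elems[flip, 3] = elems[flip, 3].copy(), elems[flip, 2].copy()
    return elems


def _boundary_faces(elems: np.ndarray) -> list[tuple[tuple[int, int, int], int, int]]:
    """Corner faces appearing exactly once, with owning element and opposite
    local vertex (for outward orientation)."""
    face_local = ((1, 2, 3, 0), (0, 3, 2, 1), (0, 1, 3, 2), (0, 2, 1, 3))
    seen: dict[tuple[int, int, int], tuple[tuple[int, ...], int, int]] = {}
    for e, tet in enumerate(elems[:, :4]):
        for fl in face_local:
            tri = (tet[fl[0]], tet[fl[1]], tet[fl[2]])
            key = tuple(sorted(tri))
            if key in seen:
                seen[key] = None  # interior
            else:
                seen[key] = (tri, e, tet[fl[3]])
    return [v for v in seen.values() if v is not None]


def _orient_outward(nodes: np.ndarray, tri: list[int], opp: int) -> list[int]:
    x0, x1, x2 = nodes[tri[0]], nodes[tri[1]], nodes[tri[2]]
    n = np.cross(x1 - x0, x2 - x0)
    if np.dot(n, (x0 + x1 + x2) / 3.0 - nodes[opp]) < 0:
        tri = [tri[0], tri[2], tri[1]]
    return tri


def _add_midedge_nodes(
    nodes: list[np.ndarray],
    elems: np.ndarray,
    position_of_edge,
) -> tuple[np.ndarray, np.ndarray, dict[tuple[int, int], int]]:
    """Promote a P1 tet mesh to P2, creating one node per edge via
    ``position_of_edge(id_lo, id_hi)``."""
    edge_ids: dict[tuple[int, int], int] = {}
    elems10 = np.empty((elems.shape[0], 10), dtype=int)
    elems10[:, :4] = elems[:, :4]
    for e, tet in enumerate(elems[:, :4]):
        for k, (i, j) in enumerate(_TET_EDGES):
            key = tuple(sorted((tet[i], tet[j])))
            if key not in edge_ids:
                edge_ids[key] = len(nodes)
                nodes.append(position_of_edge(*key))
            elems10[e, 4 + k] = edge_ids[key]
    return np.array(nodes), elems10, edge_ids


def make_truncated_prolate_spheroid(
    geom: LVGeometry,
    target_elements: int = 4000,
    *,
    order: int = 2,
    n_transmural: int | None = None,
) -> TetMesh:
    """Mesh the truncated-prolate-spheroid wall.

    ``target_elements`` steers the structured grid resolution (the realized
    element count is reported in :meth:`TetMesh.statistics`).
    """
    if order not in (1, 2):
        raise ValueError("element order must be 1 or 2")

    # grid resolution from an isotropic target edge length
    b_mid = 0.5 * (geom.b_epi + geom.b_endo)
    a_mid = 0.5 * (geom.a_epi + geom.a_endo)
    L_circ = 2.0 * math.pi * b_mid
    L_mer = 0.25 * math.pi * (3.0 * (a_mid + b_mid) / 2.0 - math.sqrt(a_mid * b_mid)) * 1.3
    L_t = 0.5 * ((geom.b_epi - geom.b_endo) + (geom.a_epi - geom.a_endo))
    n_cubes = max(target_elements // 6, 8)
    h = (L_t * L_mer * L_circ / n_cubes) ** (1.0 / 3.0)
    Nt = n_transmural if n_transmural is not None else max(1, round(L_t / h))
    Nth = max(4, round(L_mer / h))
    Nph = max(8, round(L_circ / h))
    # meridional split apex->equator / equator->base, equator ring exact
    hemisphere = geom.c_trunc == 0.0  # truncation exactly at the equator
    frac_eq = 0.75
    N1 = max(2, round(Nth * frac_eq))
    N2 = 0 if hemisphere else max(1, Nth - N1)
    Nth = N1 + N2

    th_base_endo = geom.theta_base(geom.a_endo)
    th_base_epi = geom.theta_base(geom.a_epi)

    def theta_of(jc: float, th_base: float) -> float:
        if jc <= N1:
            return jc / N1 * (math.pi / 2.0)
        return math.pi / 2.0 + (jc - N1) / N2 * (th_base - math.pi / 2.0)

    if hemisphere:
        th_base_endo = th_base_epi = math.pi / 2.0

    def surface_point(jc: float, phi: float, a: float, b: float, th_base: float) -> np.ndarray:
        th = theta_of(jc, th_base)
        r = b * math.sin(th)
        return np.array([r * math.cos(phi), r * math.sin(phi), -a * math.cos(th)])

    def map_point(tc: float, jc: float, pc: float) -> np.ndarray:
        phi = 2.0 * math.pi * pc / Nph
        p_en = surface_point(jc, phi, geom.a_endo, geom.b_endo, th_base_endo)
        p_ep = surface_point(jc, phi, geom.a_epi, geom.b_epi, th_base_epi)
        t = tc / Nt
        return (1.0 - t) * p_en + t * p_ep

    # corner nodes (apex ring j=0 collapses to one node per transmural layer)
    node_id: dict[tuple[int, int, int], int] = {}
    nodes: list[np.ndarray] = []
    params: list[tuple[float, float, float]] = []  # (tc, jc, pc)
    for it in range(Nt + 1):
        for j in range(Nth + 1):
            for ip in range(Nph):
                key = (it, 0, 0) if j == 0 else (it, j, ip)
                if key in node_id:
                    node_id[(it, j, ip)] = node_id[key]
                    continue
                nid = len(nodes)
                node_id[key] = nid
                node_id[(it, j, ip)] = nid
                nodes.append(map_point(it, j, ip))
                params.append((float(it), float(j), float(ip)))

    tets: list[tuple[int, int, int, int]] = []
    for it in range(Nt):
        for j in range(Nth):
            for ip in range(Nph):
                c = np.empty((2, 2, 2), dtype=int)
                for dt in (0, 1):
                    for dj in (0, 1):
                        for dp in (0, 1):
                            c[dt, dj, dp] = node_id[(it + dt, j + dj, (ip + dp) % Nph)]
                tets.extend(_kuhn_tets(c))
    elems = _orient_positive(np.array(nodes), np.array(tets, dtype=int))

    par = np.array(params)

    def edge_param(i: int, j: int) -> tuple[float, float, float]:
        (t1, j1, p1), (t2, j2, p2) = par[i], par[j]
        if j1 == 0.0 and j2 > 0.0:
            p1 = p2
        elif j2 == 0.0 and j1 > 0.0:
            p2 = p1
        if abs(p1 - p2) > Nph / 2.0:  # periodic seam
            if p1 < p2:
                p1 += Nph
            else:
                p2 += Nph
        return 0.5 * (t1 + t2), 0.5 * (j1 + j2), 0.5 * (p1 + p2)

    if order == 2:
        node_list = list(np.array(nodes))
        all_nodes, elems, edge_ids = _add_midedge_nodes(
            node_list, elems, lambda i, j: map_point(*edge_param(i, j))
        )
        par_mid = np.array(
            [edge_param(*k) for k in edge_ids]  # insertion order == id order
        )
        par = np.vstack([par, par_mid])
    else:
        all_nodes = np.array(nodes)
        edge_ids = {}

    node_t = par[:, 0] / Nt

    # boundary facets
    faces = _boundary_faces(elems)
    facets: dict[str, list[list[int]]] = {"endo": [], "epi": [], "base": []}
    for tri, _e, opp in faces:
        tc = par[list(tri), 0]
        jc = par[list(tri), 1]
        if np.all(tc == 0.0):
            tag = "endo"
        elif np.all(tc == Nt):
            tag = "epi"
        elif np.all(jc == Nth):
            tag = "base"
        else:  # pragma: no cover - should not happen on a watertight wall
            raise RuntimeError("untagged boundary facet")
        f = _orient_outward(all_nodes, list(tri), opp)
        if order == 2:
            f += [
                edge_ids[tuple(sorted((f[0], f[1])))],
                edge_ids[tuple(sorted((f[1], f[2])))],
                edge_ids[tuple(sorted((f[0], f[2])))],
            ]
        facets[tag].append(f)

    mesh = TetMesh(
        nodes=all_nodes,
        elems=elems,
        order=order,
        facets={k: np.array(v, dtype=int) for k, v in facets.items()},
        node_t=node_t,
    )
    # equatorial rings (corner nodes at the meridional equator index N1)
    mesh.rings["equator_endo"] = np.array(
        [node_id[(0, N1, ip)] for ip in range(Nph)], dtype=int
    )
    mesh.rings["equator_epi"] = np.array(
        [node_id[(Nt, N1, ip)] for ip in range(Nph)], dtype=int
    )
    mesh.rings["base_endo"] = np.array(
        [node_id[(0, Nth, ip)] for ip in range(Nph)], dtype=int
    )
    return mesh


def box_mesh(
    lengths: tuple[float, float, float] = (1.0, 1.0, 1.0),
    divisions: tuple[int, int, int] = (2, 2, 2),
    *,
    order: int = 1,
) -> TetMesh:
    """Structured tet mesh of a box with facets tagged xmin/xmax/.../zmax
    (fixture for patch tests)."""
    nx, ny, nz = divisions
    lx, ly, lz = lengths
    shape = (nx + 1, ny + 1, nz + 1)
    nid = np.arange(np.prod(shape)).reshape(shape)
    xs, ys, zs = np.meshgrid(
        np.linspace(0, lx, nx + 1),
        np.linspace(0, ly, ny + 1),
        np.linspace(0, lz, nz + 1),
        indexing="ij",
    )
    nodes = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
    tets: list[tuple[int, int, int, int]] = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                tets.extend(_kuhn_tets(nid[i : i + 2, j : j + 2, k : k + 2]))
    elems = _orient_positive(nodes, np.array(tets, dtype=int))

    if order == 2:
        node_list = list(nodes)
        nodes, elems, edge_ids = _add_midedge_nodes(
            node_list, elems, lambda i, j: 0.5 * (node_list[i] + node_list[j])
        )
    else:
        edge_ids = {}

    tol = 1e-12 * max(lx, ly, lz)
    planes = {
        "xmin": (0, 0.0),
        "xmax": (0, lx),
        "ymin": (1, 0.0),
        "ymax": (1, ly),
        "zmin": (2, 0.0),
        "zmax": (2, lz),
    }
    facets: dict[str, list[list[int]]] = {k: [] for k in planes}
    for tri, _e, opp in _boundary_faces(elems):
        for tag, (ax, val) in planes.items():
            if np.all(np.abs(nodes[list(tri), ax] - val) < 1e-9 + tol):
                f = _orient_outward(np.asarray(nodes), list(tri), opp)
                if order == 2:
                    f += [
                        edge_ids[tuple(sorted((f[0], f[1])))],
                        edge_ids[tuple(sorted((f[1], f[2])))],
                        edge_ids[tuple(sorted((f[0], f[2])))],
                    ]
                facets[tag].append(f)
                break
    return TetMesh(
        nodes=np.asarray(nodes, dtype=float),
        elems=elems,
        order=order,
        facets={k: np.array(v, dtype=int) for k, v in facets.items() if v},
        node_t=np.full(len(nodes), np.nan),
    )
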