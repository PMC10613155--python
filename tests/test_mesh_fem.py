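"""Geometry, fiber architecture and finite element mechanics."""

import math

import numpy as np
import pytest

from cardiogr.fem import Discretization
from cardiogr.lv_model import LVModel, assign_fiber_field
from cardiogr.mesh import LVGeometry, box_mesh, make_truncated_prolate_spheroid
from cardiogr.params import human_lv_mixture


def ellipsoid_cap_volume(a: float, b: float, c: float) -> float:
    """Volume of the rotational ellipsoid (semi-axes b, b, a) below z = c."""
    return math.pi * b * b * (c - c**3 / (3 * a * a) + 2 * a / 3)


class TestLVMesh:
    def test_wall_volume_matches_analytic(self):
        geom = LVGeometry()
        exact = ellipsoid_cap_volume(
            geom.a_epi, geom.b_epi, geom.c_trunc
        ) - ellipsoid_cap_volume(geom.a_endo, geom.b_endo, geom.c_trunc)
        mesh = make_truncated_prolate_spheroid(geom, 2000, order=2)
        vol = Discretization(mesh).volume()
        assert vol == pytest.approx(exact, rel=0.02)
        # curved quadratic elements resolve the shell nearly exactly
        assert vol == pytest.approx(exact, rel=1e-3)

    def test_equatorial_wall_thickness_and_diameter(self):
        geom = LVGeometry()
        mesh = make_truncated_prolate_spheroid(geom, 1500, order=2)
        en = mesh.nodes[mesh.rings["equator_endo"]]
        ep = mesh.nodes[mesh.rings["equator_epi"]]
        thickness = np.linalg.norm(ep - en, axis=1).mean()
        assert thickness == pytest.approx(11e-3, rel=1e-6)
        d = max(
            np.linalg.norm(en[i] - en[j])
            for i in range(len(en))
            for j in range(i + 1, len(en))
        )
        assert d == pytest.approx(38e-3, rel=1e-6)

    def test_boundary_tagged_watertight(self):
        mesh = make_truncated_prolate_spheroid(LVGeometry(), 800, order=1)
        # every boundary facet belongs to exactly one tag
        n_boundary = sum(len(f) for f in mesh.facets.values())
        from cardiogr.mesh import _boundary_faces

        assert n_boundary == len(_boundary_faces(mesh.elems))


@pytest.fixture(scope="module")
def frames():
    mesh = make_truncated_prolate_spheroid(LVGeometry(), 1500, order=2)
    disc = Discretization(mesh)
    f0 = assign_fiber_field(disc, mesh.node_t)
    t = np.clip(disc.interpolate(mesh.node_t), 0, 1)
    return disc, f0, t


class TestFiberField:

    def test_unit_length(self, frames):
        _, f0, _ = frames
        assert np.allclose(np.linalg.norm(f0, axis=2), 1.0, atol=1e-12)

    def test_helix_angle_endpoints_and_midwall(self, frames):
        disc, f0, t = frames
        X = disc.gp_x
        zhat = np.array([0.0, 0.0, 1.0])
        circ = np.cross(np.broadcast_to(zhat, X.shape), X)
        circ /= np.linalg.norm(circ, axis=1, keepdims=True)
        cosang = np.abs(np.einsum("ni,ni->n", f0[:, 0], circ))
        ang = np.degrees(np.arccos(np.clip(cosang, 0, 1)))
        # away from the apex the helix angle follows the transmural rule
        r = np.linalg.norm(X[:, :2], axis=1)
        ok = r > 8e-3
        expected = np.abs(60.0 - 120.0 * t)
        assert np.abs(ang[ok] - expected[ok]).max() < 7.0  # deg, interpolation
        mid = ok & (np.abs(t - 0.5) < 0.02)
        if mid.any():
            assert np.abs(ang[mid]).max() < 5.0

    def test_collagen_families_in_plane_at_stated_angles(self, frames):
        _, f0, _ = frames
        m, s = f0[:, 1], f0[:, 2]
        assert np.abs(np.einsum("ni,ni->n", m, s)).max() < 1e-10
        for k, expected in ((3, 45.0), (4, 45.0)):
            c = np.einsum("ni,ni->n", f0[:, k], m)
            assert np.allclose(np.degrees(np.arccos(c)), expected, atol=1e-6)


@pytest.fixture(scope="module")
def cube_model():
    mix = human_lv_mixture()
    mesh = box_mesh((1e-2, 1e-2, 1e-2), (2, 2, 2), order=2)
    fixed = np.zeros(3 * mesh.n_nodes, bool)
    for n in np.unique(mesh.facets["xmin"]):
        fixed[3 * n : 3 * n + 3] = True
    model = LVModel(
        mesh=mesh, mix=mix, pressure_tag="xmax", c_base=0.0, c_p=0.0, fixed_dofs=fixed
    )
    model.set_prestretch_scale(0.0)
    return model


class TestAssembly:
    def test_zero_load_zero_residual(self, cube_model):
        u = np.zeros(cube_model.disc.n_dofs)
        R, _ = cube_model.assemble(u, 0.0, active_scale=0.0)
        assert np.abs(R).max() < 1e-10

    def test_tangent_matches_residual_derivative(self, cube_model, rng):
        model = cube_model
        u = 2e-4 * rng.standard_normal(model.disc.n_dofs)
        p = 1e3
        R, K = model.assemble(u, p, active_scale=0.0)
        v = rng.standard_normal(model.disc.n_dofs)
        v /= np.linalg.norm(v)
        h = 1e-8
        Rp, _ = model.assemble(u + h * v, p, active_scale=0.0, need_tangent=False)
        Rm, _ = model.assemble(u - h * v, p, active_scale=0.0, need_tangent=False)
        fd = (Rp - Rm) / (2 * h)
        Kv = K @ v
        assert np.linalg.norm(Kv - fd) < 1e-5 * np.linalg.norm(Kv)

    def test_follower_pressure_patch(self, cube_model):
        """Reaction force equals pressure times the deformed face area."""
        model = cube_model
        p = 2e3
        u, rep = model.solve(p, active_scale=0.0)
        assert rep.converged
        R, _ = model.assemble(u, p, active_scale=0.0, need_tangent=False)
        xmin = np.unique(model.mesh.facets["xmin"])
        reaction = R.reshape(-1, 3)[xmin].sum(axis=0)
        st = model.surfaces["xmax"]
        x = model.deformed_nodes(u)
        xf = x[st.facets]
        g = np.einsum("fai,qaj->fqij", xf, st.dN)
        from cardiogr.fem import _tri_quadrature

        qw = _tri_quadrature(2)[1]
        area_vec = np.einsum("q,fqi->i", qw, np.cross(g[..., 0], g[..., 1]))
        expected = p * np.linalg.norm(area_vec)
        assert abs(np.linalg.norm(reaction) - expected) < 1e-6 * expected

    def test_newton_quadratic_convergence(self, cube_model):
        _, rep = cube_model.solve(3e3, active_scale=0.0)
        assert rep.converged
        n = rep.residual_norms
        # final contraction far beyond linear (consistent tangent)
        assert n[-1] < 1e-4 * n[-2]

    def test_zero_load_converges_immediately(self, cube_model):
        u, rep = cube_model.solve(0.0, active_scale=0.0)
        assert rep.converged and rep.iterations <= 2
        assert np.abs(u).max() < 1e-12


class TestSphereInflation:
    """Inflation of a thick-walled (nearly) incompressible neo-Hookean
    hemisphere against the closed-form pressure-radius relation."""

    def test_matches_closed_form(self, sphere_fixture):
        a_fem, a_oracle, A = sphere_fixture
        assert abs((a_fem - A) / (a_oracle - A) - 1.0) < 0.01


class TestMeshRefinement:
    def test_static_metrics_stable_under_refinement(self):
        from cardiogr.params import MMHG
        from cardiogr.scenarios import measure_metrics

        mix = human_lv_mixture()
        vals = {}
        for target in (2000, 4000):
            model = LVModel.from_geometry(
                LVGeometry(), mix, target_elements=target, order=1
            )
            u, rep = model.solve(120 * MMHG)
            assert rep.converged
            vals[target] = measure_metrics(model, u)
        for key in ("thickness", "diameter"):
            assert vals[2000][key] == pytest.approx(vals[4000][key], rel=0.02)
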