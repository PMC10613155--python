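"""Shared fixtures.

The finite element baseline (prestress + G&R settling on a coarse linear
mesh) is expensive, so it is built once per session and shared by the
prestress, scenario and acceptance tests.  Scenario runs copy the evolving
fields and never mutate the baseline.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiogr.params import human_lv_mixture
from cardiogr.scenarios import ScenarioConfig, prepare_baseline


@pytest.fixture(scope="session")
def mix():
    return human_lv_mixture()


@pytest.fixture(scope="session")
def scenario_config():
    """Scaled-down FEM study conditions shared by all scenario tests:
    coarse linear mesh, 2.5-day G&R step, prestress to 0.01 mm."""
    return ScenarioConfig(
        model="fem",
        target_elements=1500,
        order=1,
        dt=2.5,
        eps_pre_mm=0.01,
        settle_steps=100,
        horizon=2000.0,
    )


@pytest.fixture(scope="session")
def fem_baseline(scenario_config):
    return prepare_baseline(scenario_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230723)


@pytest.fixture(scope="session")
def sphere_fixture():
    """Thick-walled hemisphere inflation: FEM inner radius vs the closed-form
    incompressible neo-Hookean pressure-radius relation at p = 5 kPa.

    Returns ``(a_fem, a_oracle, A)`` with A the reference inner radius.
    """
    from scipy.integrate import quad
    from scipy.optimize import brentq

    from cardiogr.lv_model import LVModel
    from cardiogr.mesh import LVGeometry, make_truncated_prolate_spheroid
    from cardiogr.params import ElastinParams, FiberConstituentParams, MixtureParams

    A, B = 19e-3, 30e-3
    rho0, mu = 1050.0, 45e3
    eps = 1e-5
    fib = lambda n: FiberConstituentParams(  # vanishing fiber content
        name=n, a=1e-4, b=1.0, lambda_h=1.001, xi0=eps, k_gain=0.01, T_survival=10.0
    )
    mix = MixtureParams(
        rho0_total=rho0,
        kappa=200 * mu,
        elastin=ElastinParams(c1=mu / (2 * rho0 * (1 - 5 * eps)), xi0=1 - 5 * eps),
        myocyte=fib("m"),
        collagen=tuple(fib(f"c{i}") for i in range(4)),
        lambda_act0=1.0,
    )

    def p_of_inner_radius(a):
        # incompressible neo-Hooke: p = int 2 mu/r (lam_t^2 - lam_r^4 ... ) dr
        b = (B**3 - A**3 + a**3) ** (1.0 / 3.0)

        def integrand(r):
            R = (r**3 - a**3 + A**3) ** (1.0 / 3.0)
            return 2 * mu / r * ((r / R) ** 2 - (R / r) ** 4)

        return quad(integrand, a, b, limit=200)[0]

    geom = LVGeometry(a_epi=B, b_epi=B, a_endo=A, b_endo=A, c_trunc=0.0)
    mesh = make_truncated_prolate_spheroid(geom, 1500, order=2)
    fixed = np.zeros(3 * mesh.n_nodes, bool)
    fixed[3 * np.unique(mesh.facets["base"]) + 2] = True  # symmetry plane rollers
    apex = int(np.argmin(mesh.nodes[:, 2]))
    fixed[3 * apex] = True
    fixed[3 * apex + 1] = True
    slice_nodes = np.where(np.abs(mesh.nodes[:, 1]) < 1e-9)[0]
    fixed[3 * slice_nodes + 1] = True  # kill the free rotation about z
    model = LVModel(
        mesh=mesh, mix=mix, pressure_tag="endo", c_base=0.0, c_p=0.0, fixed_dofs=fixed
    )
    model.set_prestretch_scale(0.0)
    p = 5e3
    u, rep = model.solve(p, active_scale=0.0)
    assert rep.converged
    endo = np.unique(mesh.facets["endo"])
    a_fem = float(np.linalg.norm(model.deformed_nodes(u)[endo], axis=1).mean())
    a_oracle = brentq(lambda a: p_of_inner_radius(a) - p, A * 1.0001, A * 2)
    return a_fem, a_oracle, A


def random_admissible_F(rng: np.random.Generator, n: int, scale: float = 0.08) -> np.ndarray:
    """Random deformation gradients near identity with det > 0."""
    F = np.tile(np.eye(3), (n, 1, 1)) + scale * rng.standard_normal((n, 3, 3))
    bad = np.linalg.det(F) < 0.3
    while np.any(bad):
        F[bad] = np.eye(3) + scale * rng.standard_normal((bad.sum(), 3, 3))
        bad = np.linalg.det(F) < 0.3
    return F


def random_unit_vectors(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    v = rng.standard_normal(shape + (3,))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)
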