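"""Turnover and remodeling evolution equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiogr.constitutive import PointFields, fiber_stress_batch
from cardiogr.gnr import (
    ConstituentState,
    GnRStepConfig,
    active_stretch_update,
    degradation_rate,
    net_mass_production_rate,
    remodeling_gradient,
    remodeling_rate,
    step_gnr,
)
from cardiogr.lv_model import homeostatic_stresses
from cardiogr.reduced import PointDriveProtocol, drive_material_point, planar_fiber_set

EX = np.array([1.0, 0.0, 0.0])


class TestMassRates:
    def test_homeostasis_is_fixed_point(self):
        assert net_mass_production_rate(630.0, 0.01, 22e3, 22e3) == 0.0

    def test_hand_evaluated_growth(self):
        # rho0 k (sigma - sigma_h)/sigma_h with a 10% overstress
        rate = net_mass_production_rate(630.0, 0.1 / 10.0, 1.1 * 22e3, 22e3)
        assert rate == pytest.approx(0.63, rel=1e-12)

    def test_understress_causes_atrophy(self):
        assert net_mass_production_rate(630.0, 0.01, 20e3, 22e3) < 0.0

    def test_degradation_poisson(self):
        assert degradation_rate(630.0, 10.0) == pytest.approx(-63.0)
        assert degradation_rate(0.0, 10.0) == 0.0

    def test_production_balances_degradation_at_homeostasis(self):
        # net = 0, so true production = net - degradation = +rho0/T
        rho0, T = 630.0, 10.0
        net = net_mass_production_rate(rho0, 0.01, 22e3, 22e3)
        assert net - degradation_rate(rho0, T) == pytest.approx(rho0 / T)

    def test_zero_sigma_h_rejected(self):
        with pytest.raises(ValueError):
            net_mass_production_rate(630.0, 0.01, 22e3, 0.0)


class TestRemodelingRate:
    def state(self):
        return ConstituentState(rho0=630.0, lambda_r=1.0 / 1.1, sigma_h=22e3)

    def test_homeostatic_fixed_point(self):
        assert remodeling_rate(self.state(), 22e3, 5e5, 1.21, 0.0, 10.0) == 0.0

    def test_overstress_lengthens_fiber(self):
        rate = remodeling_rate(self.state(), 24e3, 5e5, 1.21, 0.63, 10.0)
        assert rate > 0.0

    def test_degenerate_compression_rate_is_zero(self):
        assert remodeling_rate(self.state(), 0.0, 0.0, 0.9, -0.63, 10.0) == 0.0


class TestRemodelingGradient:
    def test_identity(self):
        assert np.allclose(remodeling_gradient(1.0, EX), np.eye(3))

    def test_eigenstructure(self):
        Fr = remodeling_gradient(2.0, EX)
        w = np.sort(np.linalg.eigvalsh(Fr))
        assert w == pytest.approx([2**-0.5, 2**-0.5, 2.0])
        assert np.linalg.det(Fr) == pytest.approx(1.0, abs=1e-14)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=0.5, max_value=2.0))
    def test_isochoric_for_any_stretch(self, lam_r):
        f0 = np.array([0.6, 0.8, 0.0])
        assert abs(np.linalg.det(remodeling_gradient(lam_r, f0)) - 1.0) < 1e-12


class TestActiveStretchUpdate:
    def test_unchanged_for_equal_stretch(self):
        assert active_stretch_update(1.0, 1.2, 1.2) == 1.0

    def test_doubling_adds_log_two(self):
        assert active_stretch_update(1.0, 1.0, 2.0) == pytest.approx(1.0 + math.log(2))

    def test_round_trip_path_independent(self):
        lam = active_stretch_update(0.9, 1.0, 2.0)
        lam = active_stretch_update(lam, 2.0, 1.0)
        assert lam == pytest.approx(0.9)

    def test_proportional_mode(self):
        assert active_stretch_update(0.9, 1.0, 2.0, mode="proportional") == pytest.approx(1.8)


class TestStepGnR:
    def test_homeostatic_state_is_stationary(self, mix):
        fields = PointFields.homeostatic(planar_fiber_set(), mix)
        sigma_h = homeostatic_stresses(mix)
        cfg = GnRStepConfig(dt=0.5)
        out = step_gnr(fields, np.eye(3)[None], sigma_h, mix, cfg)
        assert np.allclose(out.rho0, fields.rho0, rtol=1e-12)
        assert np.allclose(out.lambda_r, fields.lambda_r, rtol=1e-12)

    def test_default_step_is_twentieth_of_shortest_survival(self, mix):
        assert GnRStepConfig.default_for(mix).dt == pytest.approx(0.5)

    def test_negative_density_aborts(self, mix):
        fields = PointFields.homeostatic(planar_fiber_set(), mix)
        fields.rho0[:] = 1e-9
        sigma_h = homeostatic_stresses(mix)
        F = np.diag([0.7, 1.2, 1.2])[None]  # strong understress -> atrophy
        cfg = GnRStepConfig(dt=1e6)
        with pytest.raises(RuntimeError):
            step_gnr(fields, F, sigma_h, mix, cfg)


def relaxation_trajectory(mix, scheme, dt, lam=1.004, duration=None):
    """Frozen-stretch stress relaxation of the full mixture point."""
    T = mix.myocyte.T_survival
    duration = duration or 5 * T
    proto = PointDriveProtocol(
        control="stretch",
        schedule=[(0.0, lam)],
        duration=duration,
        dt=dt,
        scheme=scheme,
    )
    return drive_material_point(proto, mix)


def analog_rate_myocyte(mix) -> float:
    """Closed-form linearized relaxation rate of the myocyte at frozen total
    stretch (independent arithmetic, no package kernels).

    The passive part relaxes with the dashpot rate 1/T; the motor unit
    (active stress) scales with the evolving myocyte mass, which adds the
    slow term -k sigma_act0/sigma_h: rate = (1/T)(1 - k T sigma_act0/sigma_h).
    """
    import math

    passive = 2 * 1050.0 * 1.21 * 7.6 * 0.21 * math.exp(11.4 * 0.21**2)
    active0 = 22e3 - passive
    k, T = mix.myocyte.k_gain, mix.myocyte.T_survival
    return (1.0 / T) * (1.0 - k * T * active0 / 22e3)


class TestMaxwellAnalog:
    """At frozen total stretch, the linearized remodeling law is a Maxwell
    element: stress deviations decay exponentially (rate 1/T for passive
    constituents; the mass-scaled motor unit slows the myocyte slightly)."""

    def test_myocyte_relaxation_matches_closed_form(self, mix):
        df = relaxation_trajectory(mix, "trapezoidal", dt=0.05)
        sig = df["sigma_myocyte"].to_numpy()
        t = df["time"].to_numpy()
        dev0 = sig[0] - 22e3
        expected = 22e3 + dev0 * np.exp(-analog_rate_myocyte(mix) * t)
        assert np.abs(sig - expected).max() < 0.01 * abs(dev0)

    def test_collagen_relaxation_time_constant_is_survival_time(self, mix):
        sigma_h_c = 206536.2393
        df = relaxation_trajectory(mix, "trapezoidal", dt=0.05)
        sig = df["sigma_collagen_fiber"].to_numpy()
        t = df["time"].to_numpy()
        dev0 = sig[0] - sigma_h_c
        expected = sigma_h_c + dev0 * np.exp(-t / mix.collagen[0].T_survival)
        # small perturbations: collagen is stiff, so keep only the window
        # where the linearization holds (first two time constants)
        w = t <= 2 * mix.collagen[0].T_survival
        assert np.abs(sig[w] - expected[w]).max() < 0.01 * abs(dev0)

    def test_euler_and_trapezoidal_agree(self, mix):
        # the study integrates with forward Euler at dt = T/20 and verifies
        # with an implicit trapezoidal rule
        df_e = relaxation_trajectory(mix, "forward-euler", dt=0.5)
        df_t = relaxation_trajectory(mix, "trapezoidal", dt=0.5)
        for col in ("lambda_r_myocyte", "lambda_r_collagen_fiber"):
            a, b = df_e[col].to_numpy(), df_t[col].to_numpy()
            assert np.abs(a - b).max() < 1e-3 * np.abs(b).max()

    def test_euler_first_order_convergence(self, mix):
        # Richardson: halving dt roughly halves the error vs a fine
        # trapezoidal reference at day 50
        ref = relaxation_trajectory(mix, "trapezoidal", dt=0.05, duration=50.0)
        e = {}
        for dt in (1.0, 0.5):
            df = relaxation_trajectory(mix, "forward-euler", dt=dt, duration=50.0)
            e[dt] = abs(
                df["lambda_r_myocyte"].iloc[-1] - ref["lambda_r_myocyte"].iloc[-1]
            )
        ratio = e[1.0] / e[0.5]
        assert 1.5 < ratio < 2.6
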