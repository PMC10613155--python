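"""Constitutive point operations: invariants, energies, stresses, tangents."""

import math

import numpy as np
import pytest

from cardiogr.constitutive import (
    PointFields,
    fiber_stress_batch,
    active_fiber_stress,
    active_stress_factor,
    constituent_fiber_cauchy_stress,
    elastin_cauchy_stress,
    fiber_elastic_invariant,
    fung_fiber_energy_and_derivative,
    mixture_energy_batch,
    mixture_pk_batch,
    volumetric_penalty_stress,
    DeformationState,
)
from cardiogr.lv_model import homeostatic_stresses

from conftest import random_admissible_F, random_unit_vectors

EX = np.array([1.0, 0.0, 0.0])


class TestFiberElasticInvariant:
    def test_identity(self):
        assert fiber_elastic_invariant(np.eye(3), EX, 1.0) == pytest.approx(1.0)

    def test_uniaxial_stretch(self):
        lam = 1.2
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        assert fiber_elastic_invariant(F, EX, 1.0) == pytest.approx(1.44)

    def test_prestressed_initial_condition(self):
        # lambda_r = 1/lambda_h puts the fiber at its homeostatic elastic
        # stretch in the undeformed reference configuration
        assert fiber_elastic_invariant(np.eye(3), EX, 1.0 / 1.1) == pytest.approx(1.21)

    @pytest.mark.parametrize(
        "f0,lam_r",
        [(np.array([1.0, 1.0, 0.0]), 1.0), (EX, 0.0), (EX, -1.0)],
    )
    def test_rejects_invalid_input(self, f0, lam_r):
        with pytest.raises(ValueError):
            fiber_elastic_invariant(np.eye(3), f0, lam_r)


class TestFungFiberEnergy:
    def test_zero_strain(self, mix):
        assert fung_fiber_energy_and_derivative(1.0, mix.myocyte) == (0.0, 0.0)

    def test_compression_excluded(self, mix):
        assert fung_fiber_energy_and_derivative(0.9, mix.myocyte) == (0.0, 0.0)

    def test_derivative_value(self, mix):
        # dW/dI4 = a (I4-1) exp(b (I4-1)^2) at the myocyte homeostatic stretch
        _, dW = fung_fiber_energy_and_derivative(1.21, mix.myocyte)
        assert dW == pytest.approx(7.6 * 0.21 * math.exp(11.4 * 0.0441), rel=1e-12)

    def test_derivative_consistent_with_energy(self, mix):
        h = 1e-7
        for i4e in (1.05, 1.2, 1.4):
            wp = fung_fiber_energy_and_derivative(i4e + h, mix.collagen[0])[0]
            wm = fung_fiber_energy_and_derivative(i4e - h, mix.collagen[0])[0]
            dW = fung_fiber_energy_and_derivative(i4e, mix.collagen[0])[1]
            assert dW == pytest.approx((wp - wm) / (2 * h), rel=1e-6)


class TestActiveTone:
    def test_bounds_and_midpoint(self, mix):
        p = mix.myocyte
        assert active_stress_factor(0.8, p) == pytest.approx(0.0)
        assert active_stress_factor(1.4, p) == pytest.approx(1.0)
        assert active_stress_factor(1.1, p) == pytest.approx(0.75)

    def test_clamped_outside_range(self, mix):
        p = mix.myocyte
        assert active_stress_factor(0.5, p) == 0.0
        assert active_stress_factor(1.8, p) == 1.0

    def test_scales_with_mass_ratio(self, mix):
        p = mix.myocyte
        s1 = active_fiber_stress(1.1, 1.0, p)
        assert active_fiber_stress(1.1, 1.3, p) == pytest.approx(1.3 * s1)


class TestElastinStress:
    def test_undeformed_is_zero(self, mix):
        s = elastin_cauchy_stress(np.eye(3), np.eye(3), mix.elastin, 315.0)
        assert np.allclose(s, 0.0, atol=1e-12)

    def test_objectivity_under_rotation(self, mix, rng):
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=3).as_matrix()
        s = elastin_cauchy_stress(R, np.eye(3), mix.elastin, 315.0)
        assert np.allclose(s, 0.0, atol=1e-9)

    def test_matches_incompressible_neo_hooke(self, mix):
        # prestretch alone: sigma = mu dev(B) with B = G^2, mu = 2 rho c1
        alpha = 1.2
        G = np.diag([alpha, alpha**-0.5, alpha**-0.5])
        rho_e = 315.0
        s = elastin_cauchy_stress(np.eye(3), G, mix.elastin, rho_e)
        mu = 2.0 * rho_e * mix.elastin.c1
        B = G @ G
        expected = mu * (B - np.trace(B) / 3.0 * np.eye(3))
        assert np.allclose(s, expected, rtol=1e-12)
        assert abs(np.trace(s)) < 1e-8 * np.abs(s).max()


class TestVolumetricPenalty:
    def test_zero_at_mass_ratio(self):
        F = 1.1 ** (1.0 / 3.0) * np.eye(3)
        P = volumetric_penalty_stress(F, 1.1, 150e3)
        assert np.allclose(P, 0.0, atol=1e-6)

    def test_identity_reference(self):
        assert np.allclose(volumetric_penalty_stress(np.eye(3), 1.0, 150e3), 0.0)

    def test_matches_symbolic_derivative(self):
        F = np.diag([1.1, 1.0, 1.0])
        kappa, m = 150e3, 1.0
        J = 1.1
        expected = kappa * (J - m) * J * np.linalg.inv(F).T
        assert np.allclose(volumetric_penalty_stress(F, m, kappa), expected, rtol=1e-12)


class TestConstituentStress:
    def test_myocyte_homeostatic_value(self, mix):
        state = DeformationState(
            F=np.eye(3), f0=EX, lambda_r=np.array([1.0 / 1.1]), G3D=np.eye(3)
        )
        sigma = constituent_fiber_cauchy_stress(state, mix.myocyte, mix)
        assert sigma == pytest.approx(22e3, rel=1e-9)

    def test_compression_gives_zero_passive(self, mix):
        state = DeformationState(
            F=0.95 * np.eye(3), f0=EX, lambda_r=np.array([1.0]), G3D=np.eye(3)
        )
        sigma = constituent_fiber_cauchy_stress(state, mix.collagen[0], mix)
        assert sigma == 0.0

    def test_collagen_homeostatic_regression_constant(self, mix):
        # frozen set point of the calibrated stress convention
        assert homeostatic_stresses(mix)[1] == pytest.approx(206536.2393, rel=1e-9)


class TestMixtureStress:
    def make_fields(self, mix, rng, n):
        f0 = random_unit_vectors(rng, (n, 5))
        fields = PointFields.homeostatic(f0, mix)
        fields.lambda_r *= rng.uniform(0.92, 1.08, (n, 5))
        return fields

    def test_kirchhoff_symmetry(self, mix, rng):
        # angular momentum balance: P F^T symmetric
        F = random_admissible_F(rng, 50)
        fields = self.make_fields(mix, rng, 50)
        P, _ = mixture_pk_batch(F, fields, mix, with_tangent=False)
        PFt = np.einsum("nij,nkj->nik", P, F)
        asym = np.abs(PFt - PFt.transpose(0, 2, 1)).max()
        assert asym < 1e-8 * np.abs(PFt).max()

    def test_matches_energy_gradient(self, mix, rng):
        F = random_admissible_F(rng, 100)
        fields = self.make_fields(rng=rng, mix=mix, n=100)
        P, _ = mixture_pk_batch(F, fields, mix, with_tangent=False)
        h = 1e-6
        Pfd = np.zeros_like(P)
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[:, i, j] += h
                Fm[:, i, j] -= h
                Pfd[:, i, j] = (
                    mixture_energy_batch(Fp, fields, mix)
                    - mixture_energy_batch(Fm, fields, mix)
                ) / (2 * h)
        assert np.abs(P - Pfd).max() < 1e-5 * np.abs(P).max()

    def test_tangent_matches_stress_gradient(self, mix, rng):
        F = random_admissible_F(rng, 10)
        fields = self.make_fields(mix, rng, 10)
        _, A = mixture_pk_batch(F, fields, mix)
        h = 1e-6
        for k in range(3):
            for l in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[:, k, l] += h
                Fm[:, k, l] -= h
                dP = (
                    mixture_pk_batch(Fp, fields, mix, with_tangent=False)[0]
                    - mixture_pk_batch(Fm, fields, mix, with_tangent=False)[0]
                ) / (2 * h)
                assert np.abs(A[:, :, :, k, l] - dP).max() < 1e-5 * np.abs(A).max()

    def test_fiber_stress_continuous_at_tension_switch(self, mix):
        # passive fiber stress is zero in compression and approaches zero
        # continuously from the tension side of I4e = 1
        fields = PointFields.homeostatic(np.tile(EX, (1, 5, 1)), mix)
        fields.lambda_r[:] = 1.0
        eps = 1e-8
        lo = fiber_stress_batch(
            np.diag([1 - eps, 1, 1])[None], fields, mix, active_scale=0.0
        )[0]
        hi = fiber_stress_batch(
            np.diag([1 + eps, 1, 1])[None], fields, mix, active_scale=0.0
        )[0]
        assert np.all(lo == 0.0)
        # a discontinuity at the switch would be O(kPa); the one-sided limit
        # scales linearly with the offset from I4e = 1
        assert np.abs(hi).max() < 0.1  # Pa

    def test_penalty_enforces_mass_ratio_with_increasing_kappa(self, mix, rng):
        # |J - rho0(s)/rho0(0)| decreases monotonically in kappa under a
        # hydrostatic load
        import dataclasses

        from scipy.optimize import brentq

        fields = PointFields.homeostatic(np.tile(EX, (1, 5, 1)), mix)
        fields.rho0 *= 1.2  # grown point: target J above 1
        target = fields.mass_ratio(mix)[0]
        errs = []
        for kappa in (15e3, 150e3, 1500e3):
            m = dataclasses.replace(mix, kappa=kappa)

            def hydro(j):
                F = j ** (1.0 / 3.0) * np.eye(3)[None]
                P, _ = mixture_pk_batch(F, fields, m, with_tangent=False)
                return np.trace(P[0] @ F[0].T)

            j_eq = brentq(hydro, 0.5, 2.0)
            errs.append(abs(j_eq - target))
        assert errs[0] > errs[1] > errs[2]
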