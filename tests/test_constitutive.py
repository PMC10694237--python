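"""Constitutive-law oracles: deposition tensors, energies, Cauchy stress."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cmmfit as cm
from cmmfit.constitutive import DiagonalMixture, volumetric_energy


def random_mp(rng):
    return cm.MaterialParameters(
        c_e=rng.uniform(2, 50), k1_c=rng.uniform(2, 100),
        k2_c=rng.uniform(0, 3), beta_deg=rng.uniform(10, 80),
        k1_m=rng.uniform(2, 100), k2_m=rng.uniform(0, 3))


class TestDepositionTensor:
    def test_unit_deposition_is_identity(self):
        ds = cm.DepositionStretches.identity()
        for c in ("e", "c0", "c1", "m"):
            G = cm.deposition_tensor(c, ds, beta_deg=39.7)
            assert np.allclose(G, np.eye(3), atol=1e-14)

    def test_elastin_diagonal_form(self):
        ds = cm.DepositionStretches(G_theta_e=1.05, G_z_e=1.31)
        G = cm.deposition_tensor("e", ds)
        assert np.allclose(np.diag(G), [1 / (1.05 * 1.31), 1.05, 1.31])
        assert np.allclose(G - np.diag(np.diag(G)), 0)
        assert abs(np.linalg.det(G) - 1) < 1e-12

    def test_muscle_fiber_tensor(self):
        ds = cm.DepositionStretches(G_m=1.45)
        G = cm.deposition_tensor("m", ds)
        expected = np.diag([1 / np.sqrt(1.45), 1.45, 1 / np.sqrt(1.45)])
        assert np.allclose(G, expected, atol=1e-12)

    def test_collagen_eigenstructure(self):
        ds = cm.DepositionStretches(G_c=1.10)
        frame = cm.FiberFrame.from_angle(39.7)
        G = cm.deposition_tensor("c0", ds, frame=frame)
        assert np.allclose(G, G.T)
        # eigenvalue G_c along the fiber, 1/sqrt(G_c) transverse
        assert np.allclose(G @ frame.d_c0, 1.10 * frame.d_c0)
        w = np.linalg.eigvalsh(G)
        assert np.allclose(sorted(w), sorted([1.10, 1.10 ** -0.5, 1.10 ** -0.5]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(gt=st.floats(0.5, 2.0), gz=st.floats(0.5, 2.0),
           gc=st.floats(0.5, 2.0), gm=st.floats(0.5, 2.0),
           beta=st.floats(5.0, 85.0))
    def test_determinant_one_property(self, gt, gz, gc, gm, beta):
        ds = cm.DepositionStretches(gt, gz, gc, gm)
        for c in ("e", "c0", "c1", "m"):
            G = cm.deposition_tensor(c, ds, beta_deg=beta)
            assert abs(np.linalg.det(G) - 1.0) < 1e-12

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ValueError):
            cm.DepositionStretches(G_theta_e=-0.5)


class TestEnergy:
    def test_reference_state_zero(self):
        mp = cm.MaterialParameters(10.2, 52.9, 0.39, 39.7, 10.3, 0.024)
        comp = cm.WallComposition(0.5, 0.2, 0.3)
        W = cm.strain_energy(np.eye(3), mp, cm.DepositionStretches.identity(), comp)
        assert abs(W) < 1e-14

    def test_penalty_energy_values(self):
        assert volumetric_energy(1.0, 123.0) == 0.0
        # dU/dJ at J=1 vanishes for any kappa
        h = 1e-6
        dU = (volumetric_energy(1 + h, 77.0) - volumetric_energy(1 - h, 77.0)) / (2 * h)
        assert abs(dU) < 1e-6
        assert np.isclose(volumetric_energy(2.0, 1.0), 0.5 * (1.5 - np.log(2.0)))

    def test_inverted_state_rejected(self):
        mp = cm.MaterialParameters(10.0, 10.0, 1.0, 45.0, 10.0, 1.0)
        comp = cm.WallComposition(0.5, 0.2, 0.3)
        with pytest.raises(cm.constitutive.InvertedStateError):
            cm.strain_energy(-np.eye(3), mp, cm.DepositionStretches.identity(), comp)


class TestCauchyStress:
    def test_unloaded_reference_is_stress_free(self):
        rng = np.random.default_rng(0)
        comp = cm.WallComposition(0.5, 0.2, 0.3)
        ds = cm.DepositionStretches.identity()
        for _ in range(10):
            mp = random_mp(rng)
            for mode in ("penalty", "incompressible"):
                sig = cm.cauchy_stress(np.eye(3), mp, ds, comp, mode=mode)
                assert np.allclose(sig, 0.0, atol=1e-12)

    def test_neo_hookean_uniaxial_closed_form(self):
        """Pure elastin, incompressible uniaxial: s_zz = c (lam^2 - 1/lam)."""
        comp = cm.WallComposition(1.0, 0.0, 0.0)
        mp = cm.MaterialParameters(10.2, 1.0, 0.0, 45.0, 1.0, 0.0)
        ds = cm.DepositionStretches.identity()
        lam = 1.2
        F = np.diag([lam ** -0.5, lam ** -0.5, lam])
        sig = cm.cauchy_stress(F, mp, ds, comp, mode="incompressible")
        szz = sig[2, 2] - sig[0, 0]   # pressure from zero transverse stress
        expected = 10.2 * (lam ** 2 - 1 / lam)
        assert abs(szz - expected) / expected < 1e-8
        assert np.isclose(expected, 6.188, atol=5e-4)

    def test_symmetry_random_states(self):
        rng = np.random.default_rng(1)
        comp = cm.WallComposition(0.5, 0.2, 0.3)
        ds = cm.DepositionStretches(1.05, 1.31, 1.10, 1.45)
        for _ in range(5):
            mp = random_mp(rng)
            F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0:
                continue
            sig = cm.cauchy_stress(F, mp, ds, comp, mode="penalty")
            assert np.allclose(sig, sig.T, atol=1e-10)

    def test_energy_stress_consistency_finite_difference(self):
        """sigma = (1/J) dW/dF F^T, checked by central differences."""
        comp = cm.WallComposition(0.5, 0.2, 0.3)
        mp = cm.MaterialParameters(10.2, 52.9, 0.39, 39.7, 10.3, 0.024)
        ds = cm.DepositionStretches(1.05, 1.31, 1.10, 1.45)
        rng = np.random.default_rng(2)
        F = np.diag([0.95, 1.1, 1.05]) + 0.02 * rng.standard_normal((3, 3))
        sig = cm.cauchy_stress(F, mp, ds, comp, mode="penalty")
        J = np.linalg.det(F)
        h = 1e-6
        P = np.zeros((3, 3))   # first Piola-Kirchhoff by FD
        for i in range(3):
            for k in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, k] += h
                Fm[i, k] -= h
                P[i, k] = (cm.strain_energy(Fp, mp, ds, comp)
                           - cm.strain_energy(Fm, mp, ds, comp)) / (2 * h)
        sig_fd = P @ F.T / J
        assert np.allclose(sig, sig_fd, rtol=1e-6, atol=1e-6 * np.abs(sig).max())

    def test_fiber_tension_compression_switch(self):
        """A fiber family under compression contributes no stress."""
        comp = cm.WallComposition(0.0, 0.0, 1.0)   # muscle only
        mp = cm.MaterialParameters(1e-9, 1.0, 0.0, 45.0, 10.3, 0.024)
        ds = cm.DepositionStretches.identity()
        F = np.diag([1.1, 0.9, 1.0 / 0.99])       # circumferential compression
        F = F / np.linalg.det(F) ** (1 / 3)
        sig = cm.cauchy_stress(F, mp, ds, comp, mode="incompressible")
        # I4 along theta < 1 -> only the (negligible) elastin term remains
        assert np.abs(sig).max() < 1e-6

    def test_incompressible_mode_scale_invariance(self):
        """Deviatoric response is invariant under F -> c F in exact-
        incompressible mode (unimodular evaluation)."""
        comp = cm.WallComposition(0.5, 0.2, 0.3)
        mp = cm.MaterialParameters(10.2, 52.9, 0.39, 39.7, 10.3, 0.024)
        ds = cm.DepositionStretches(1.05, 1.31, 1.10, 1.45)
        F = np.diag([0.9, 1.2, 1.0 / (0.9 * 1.2)])
        s1 = cm.cauchy_stress(F, mp, ds, comp, mode="incompressible")
        s2 = cm.cauchy_stress(1.7 * F, mp, ds, comp, mode="incompressible")
        assert np.allclose(s1, s2, atol=1e-10)

    def test_diagonal_fast_path_matches_general(self):
        comp = cm.WallComposition(0.5, 0.2, 0.3)
        mp = cm.MaterialParameters(10.2, 52.9, 0.39, 39.7, 10.3, 0.024)
        ds = cm.DepositionStretches(1.05, 1.31, 1.10, 1.45)
        mix = DiagonalMixture(mp, ds, comp)
        rng = np.random.default_rng(3)
        for _ in range(5):
            f = rng.uniform(0.7, 1.5, 2)
            f = np.array([f[0], f[1], 1.0 / (f[0] * f[1])])
            sig_fast = mix.extra_stress(f[None, :])[0]
            sig_gen = cm.cauchy_stress(np.diag(f), mp, ds, comp,
                                       mode="incompressible")
            # both leave the reaction pressure out -> compare differences
            assert np.allclose(sig_fast - sig_fast[0],
                               np.diag(sig_gen) - sig_gen[0, 0], atol=1e-9)
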