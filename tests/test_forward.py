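"""Semi-analytic solver oracles: uniaxial strip, tube inflation/unloading,
ring opening, thickness statistics."""

import numpy as np
import pytest

import cmmfit as cm
from cmmfit.forward import ArteryModel, thickness_average


@pytest.fixture(scope="module")
def elastin_only():
    comp = cm.WallComposition(1.0, 0.0, 0.0)
    mp = cm.MaterialParameters(10.2, 1.0, 0.0, 45.0, 1.0, 0.0)
    return mp, comp


class TestUniaxial:
    def test_reference_state_stress_free(self, lamb):
        mp = lamb["params"].mp
        comp = lamb["params"].comp
        s = cm.uniaxial_response([1.0], "theta", mp,
                                 cm.DepositionStretches.identity(), comp)
        assert abs(s[0]) < 1e-9

    def test_neo_hookean_oracle_along_grid(self, elastin_only):
        mp, comp = elastin_only
        lam = np.linspace(1.0, 1.6, 13)
        for direction in ("theta", "z"):
            s = cm.uniaxial_response(lam, direction, mp,
                                     cm.DepositionStretches.identity(), comp)
            expected = 10.2 * (lam ** 2 - 1 / lam)
            assert np.allclose(s, expected, rtol=1e-8, atol=1e-10)

    def test_symmetric_fibers_make_directions_exchangeable(self):
        """At beta = 45 deg with no muscle, theta and z are equivalent."""
        comp = cm.WallComposition(0.6, 0.4, 0.0)
        mp = cm.MaterialParameters(8.0, 40.0, 0.5, 45.0, 1.0, 0.0)
        ds = cm.DepositionStretches.identity()
        lam = np.linspace(1.0, 1.5, 11)
        s_t = cm.uniaxial_response(lam, "theta", mp, ds, comp)
        s_z = cm.uniaxial_response(lam, "z", mp, ds, comp)
        assert np.allclose(s_t, s_z, rtol=1e-9, atol=1e-9)

    def test_transverse_stresses_vanish(self, lamb):
        """The solved lateral stretches must null both transverse stresses."""
        from cmmfit.constitutive import DiagonalMixture
        p = lamb["params"]
        kin = cm.TestKinematics(F_release=np.diag([1.49, 0.79, 0.85]))
        lam = np.array([1.3])
        s, x = cm.uniaxial_response(lam, "theta", p.mp, p.ds, p.comp, kin,
                                    return_state=True)
        mix = DiagonalMixture(p.mp, p.ds, p.comp)
        prior = kin.prior_diag
        m_t = lam * prior[1]
        f = np.stack([x, m_t, 1.0 / (m_t * x)], axis=1)
        sig = mix.extra_stress(f)
        scale = max(1.0, np.abs(sig).max())
        assert abs(sig[0, 0] - sig[0, 2]) < 1e-8 * scale


class TestTubeSolves:
    def test_identity_fixed_point_random_materials(self, lamb):
        """p = 0, free ends, no prestretch: the reference is an equilibrium."""
        rng = np.random.default_rng(4)
        comp = cm.WallComposition(0.5, 0.2, 0.3)
        geom = lamb["geom"]
        for _ in range(3):
            mp = cm.MaterialParameters(
                c_e=rng.uniform(5, 40), k1_c=rng.uniform(5, 80),
                k2_c=rng.uniform(0, 2), beta_deg=rng.uniform(20, 70),
                k1_m=rng.uniform(5, 80), k2_m=rng.uniform(0, 2))
            snap, _ = cm.inflate_extend(
                geom, cm.LoadState(0.0, "zero_force"), mp,
                cm.DepositionStretches.identity(), comp)
            assert np.isclose(snap.d_out, geom.d_out, atol=1e-8)
            assert np.isclose(snap.d_in, geom.d_in, atol=1e-8)
            assert np.isclose(snap.lambda_z, 1.0, atol=1e-10)

    def test_pressure_monotonicity(self, lamb):
        p = lamb["params"]
        d_prev = 0.0
        for pressure in np.linspace(0.0, 20.0, 9):
            snap, _ = cm.inflate_extend(
                lamb["geom"], cm.LoadState(pressure, "fixed_stretch", 1.0),
                p.mp, p.ds, p.comp)
            assert snap.d_out >= d_prev - 1e-12
            d_prev = snap.d_out

    def test_wall_volume_conserved(self, lamb):
        """Incompressible kinematics preserve wall volume exactly."""
        p = lamb["params"]
        geom = lamb["geom"]
        v_ref = (geom.r_out ** 2 - geom.r_in ** 2) * geom.length
        for pressure, lz in ((0.0, None), (10.0, 1.0), (15.0, 1.1)):
            load = (cm.LoadState(pressure, "fixed_stretch", lz)
                    if lz is not None else cm.LoadState(pressure, "zero_force"))
            snap, _ = cm.inflate_extend(geom, load, p.mp, p.ds, p.comp)
            v = (snap.r_out ** 2 - snap.r_in ** 2) * geom.length * snap.lambda_z
            assert abs(v - v_ref) / v_ref < 1e-9

    def test_thin_wall_laplace_limit(self, elastin_only):
        """p r / t approaches the mid-wall hoop extra stress as t/r -> 0."""
        mp, comp = elastin_only
        ds = cm.DepositionStretches.identity()
        r_in, t = 50.0, 1.0   # t/r = 0.02
        geom = cm.GeometrySnapshot(d_out=2 * (r_in + t), d_in=2 * r_in)
        pressure = 0.15
        snap, profile = cm.inflate_extend(
            geom, cm.LoadState(pressure, "fixed_stretch", 1.0), mp, ds, comp)
        mid = len(profile["r"]) // 2
        hoop = profile["sigma_tt"][mid] - profile["sigma_rr"][mid]
        laplace = pressure * 0.5 * (snap.r_in + snap.r_out) / snap.thickness
        assert abs(hoop - laplace) / laplace < 0.05

    def test_unload_identity_prestretch_is_noop(self, lamb):
        p = lamb["params"]
        snap, kin, diag = cm.unload_to_exvivo(
            lamb["geom"], p.mp, cm.DepositionStretches.identity(), p.comp,
            load=lamb["load"])
        assert np.isclose(snap.d_out, lamb["geom"].d_out, atol=1e-7)
        assert np.allclose(kin.F_release, np.eye(3), atol=1e-8)
        assert np.isclose(diag["lambda_z_physiological"], 1.0, atol=1e-9)

    def test_release_gradient_volume_consistent(self, lamb_pipeline):
        f = np.diag(lamb_pipeline["kin_release"].F_release)
        assert np.all(f > 0)
        # thickness-averaged release map is near-isochoric
        assert abs(np.prod(f) - 1.0) < 0.02


class TestRingOpening:
    def test_stress_free_ring_stays_closed(self, lamb):
        p = lamb["params"]
        sector, kin, _ = cm.ring_opening(
            lamb["geom"], p.mp, cm.DepositionStretches.identity(), p.comp,
            load=lamb["load"])
        assert abs(sector.alpha_deg) < 1e-6
        assert np.allclose(kin.F_opening, np.eye(3), atol=1e-7)

    def test_energy_minimization_cross_check(self, lamb, lamb_pipeline):
        """The three integral release conditions agree with total-energy
        minimization over the same kinematic family to within 2 degrees."""
        from scipy.optimize import minimize
        p = lamb["params"]
        model: ArteryModel = lamb_pipeline["open_diag"]["model"]
        sector = lamb_pipeline["sector"]
        x0 = np.array([sector.rho_in, sector.k, sector.lambda_z_open])
        res = minimize(model.sector_energy, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 4000})
        alpha_energy = 180.0 * (1.0 - res.x[1])
        assert abs(alpha_energy - sector.alpha_deg) < 2.0

    def test_opening_angle_increases_with_elastin_prestretch(self, lamb):
        """More elastin deposition stretch -> more residual stress -> a
        wider opening after the radial cut."""
        p = lamb["params"]
        alphas = []
        for g_th, g_z in ((1.00, 1.05), (1.05, 1.31), (1.20, 1.50)):
            ds = cm.DepositionStretches(g_th, g_z, 1.10, 1.45)
            sector, _, _ = cm.ring_opening(lamb["geom"], p.mp, ds, p.comp,
                                           load=lamb["load"])
            alphas.append(sector.alpha_deg)
        assert alphas[0] < alphas[1] < alphas[2]


class TestThicknessAverage:
    @pytest.mark.parametrize("field,expected", [
        (np.full(7, 3.3), (3.3, 0.0)),
        (np.array([1.0, 2.0, 3.0]), (2.0, 1.0 / np.sqrt(3.0))),
    ])
    def test_known_values(self, field, expected):
        mean, sem = thickness_average(field)
        assert np.isclose(mean, expected[0])
        assert np.isclose(sem, expected[1], atol=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            thickness_average(np.array([]))
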