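"""Continuum adsorption free energy and the wetting-coefficient laws."""

import numpy as np
import pytest

from surfwet.units import kT
from surfwet.wetting import (MoleculeGeometry, WettingModel, area_from_kv,
                             adsorption_free_energy, cross_section_ratio,
                             fit_area_scaling, ks_kv_correlation,
                             ks_of_costheta)


def make_model(**kw):
    defaults = dict(K_s0=5.0, b_s=0.05, b_v=0.05, gamma_tilde_s=25.6,
                    gamma_tilde_v=32.7, gamma=65.0, T=300.0)
    defaults.update(kw)
    return WettingModel(**defaults)


class TestCrossSectionRatio:
    def test_sphere(self):
        assert cross_section_ratio("sphere") == 0.25

    def test_cylinder(self):
        assert cross_section_ratio("cylinder") == pytest.approx(1 / np.pi)
        assert round(cross_section_ratio("cylinder"), 2) == 0.32

    def test_scale_invariance(self):
        assert (cross_section_ratio("sphere", radius=0.2)
                == cross_section_ratio("sphere", radius=2.0))

    def test_custom_outside_interval_warns(self):
        with pytest.warns(UserWarning, match="interval"):
            cross_section_ratio("custom_ratio", ratio=0.4)

    def test_geometry_object(self):
        geo = MoleculeGeometry(A_m=2.0, shape="cylinder")
        assert geo.A_c_star == pytest.approx(2.0 / np.pi)


class TestAdsorptionFreeEnergy:
    def test_all_tensions_zero(self):
        assert adsorption_free_energy(0, 0, 0, A_c=1.0, A_c_star=0.5) == 0.0

    def test_dewetting_term_only(self):
        dg = adsorption_free_energy(30.0, 0.0, 0.0, A_c=1.0, A_c_star=0.5)
        assert dg == pytest.approx(-1.0 * 30.0 / kT(300.0))
        assert dg < 0

    def test_young_substitution_gives_costheta_form(self):
        # replacing gamma_sw by gamma_sv - gamma cos(theta) must reproduce
        # DG(theta) = DG0 + A_c* gamma cos(theta) with
        # DG0 = A_c*(gamma_sm - gamma_sv) - A_c gamma_mw
        gamma_mw, gamma_sm, gamma_sv, gamma = 30.0, 20.0, 25.0, 65.0
        A_c, A_c_star = 1.2, 0.5
        dg0 = adsorption_free_energy(gamma_mw, gamma_sm, gamma_sv,
                                     A_c, A_c_star)
        for costheta in [-0.8, -0.2, 0.0, 0.4, 0.9]:
            gamma_sw = gamma_sv - gamma * costheta
            direct = adsorption_free_energy(gamma_mw, gamma_sm, gamma_sw,
                                            A_c, A_c_star)
            via_young = dg0 + A_c_star * gamma * costheta / kT(300.0)
            assert direct == pytest.approx(via_young, rel=1e-12)


class TestKsOfCostheta:
    def test_reference_at_neutral_wetting(self):
        m, geo = make_model(), MoleculeGeometry(A_m=2.0)
        assert ks_of_costheta(0.0, m, geo) == m.K_s0

    def test_unit_exponent_arithmetic(self):
        # beta gamma A_c* = 1 and cos(theta) = -1 gives K_s/K_s0 = e
        m = make_model(gamma=1.0, T=300.0)
        geo = MoleculeGeometry(A_m=4 * kT(300.0), shape="sphere")  # A_c* = kT
        assert (ks_of_costheta(-1.0, m, geo) / m.K_s0
                == pytest.approx(np.e, rel=1e-12))

    def test_log_is_affine_in_costheta(self):
        m, geo = make_model(), MoleculeGeometry(A_m=2.0)
        x = np.linspace(-0.7, 0.7, 15)
        y = np.log(ks_of_costheta(x, m, geo))
        slope, intercept = np.polyfit(x, y, 1)
        assert np.allclose(y, slope * x + intercept, atol=1e-12)
        assert slope == pytest.approx(-m.beta * m.gamma * geo.A_c_star)

    def test_strictly_decreasing_in_costheta(self):
        m, geo = make_model(), MoleculeGeometry(A_m=2.0)
        ks = ks_of_costheta(np.linspace(-1, 1, 50), m, geo)
        assert np.all(np.diff(ks) < 0)

    def test_consistency_with_free_energy_route(self):
        # K_s = b_s exp(-beta DG_s) with the Young-substituted DG_s equals
        # the cos(theta) law exactly
        gamma_mw, gamma_sm, gamma_sv, gamma = 30.0, 20.0, 25.0, 65.0
        geo = MoleculeGeometry(A_m=2.0, shape="sphere")
        A_c = 2 * geo.A_c_star  # molecule half-buried: contact area 2 A_c*
        b_s = 0.05
        dg0 = adsorption_free_energy(gamma_mw, gamma_sm, gamma_sv, A_c,
                                     geo.A_c_star)
        m = make_model(K_s0=b_s * np.exp(-dg0), gamma=gamma)
        for costheta in [-0.9, 0.0, 0.6]:
            gamma_sw = gamma_sv - gamma * costheta
            dg = adsorption_free_energy(gamma_mw, gamma_sm, gamma_sw, A_c,
                                        geo.A_c_star)
            assert (b_s * np.exp(-dg)
                    == pytest.approx(ks_of_costheta(costheta, m, geo),
                                     rel=1e-10))


class TestAreaScaling:
    def test_two_exact_points_recovered(self):
        b, gt = 0.05, 30.0
        A = np.array([1.0, 2.5])
        K = b * np.exp(gt * A / kT(300.0))
        out = fit_area_scaling(np.column_stack([A, K]))
        assert out["b_nm"] == pytest.approx(b, rel=1e-10)
        assert out["gamma_tilde_mN_m"] == pytest.approx(gt, rel=1e-10)

    def test_constant_K_gives_zero_tension(self):
        pts = [(1.0, 3.0), (2.0, 3.0), (3.0, 3.0)]
        out = fit_area_scaling(pts)
        assert out["gamma_tilde_mN_m"] == pytest.approx(0.0, abs=1e-12)
        assert "se_gamma_tilde_mN_m" in out

    def test_nonpositive_K_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_area_scaling([(1.0, 0.0), (2.0, 1.0)])

    def test_noisy_recovery_median_within_15_percent(self):
        b, gt = 0.05, 30.0
        A = np.array([0.8, 1.6, 2.4])
        K_true = b * np.exp(gt * A / kT(300.0))
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(200):
            K = K_true * (1 + 0.05 * rng.standard_normal(3))
            out = fit_area_scaling(np.column_stack([A, K]))
            errs.append(abs(out["gamma_tilde_mN_m"] - gt) / gt)
        assert np.median(errs) < 0.15


class TestKsKvCorrelation:
    def test_symmetric_diagonal(self):
        # prefactor 1 requires gamma_tilde_s - gamma*ratio*costheta = gamma_tilde_v
        m = make_model(gamma_tilde_s=25.6, gamma_tilde_v=32.7, gamma=65.0)
        costheta = (25.6 - 32.7) / (65.0 * 0.25)
        assert -1 <= costheta <= 1
        for K_v in [0.8, 21.0, 410.0]:
            assert ks_kv_correlation(K_v, costheta, m) == pytest.approx(
                K_v, rel=1e-12)

    def test_round_trip_identity(self):
        # A_m -> K_v (area scaling) -> K_s (correlation) must equal
        # A_m -> K_s0 (area scaling) -> K_s (cos-theta law)
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = make_model(
                b_s=rng.uniform(0.01, 0.2), b_v=rng.uniform(0.01, 0.2),
                gamma_tilde_s=rng.uniform(15, 40),
                gamma_tilde_v=rng.uniform(15, 40),
                gamma=rng.uniform(50, 75))
            A_m = rng.uniform(0.5, 3.0)
            costheta = rng.uniform(-1, 1)
            geo = MoleculeGeometry(A_m=A_m, shape="sphere")
            K_v = m.b_v * np.exp(m.beta * m.gamma_tilde_v * A_m)
            K_s0 = m.b_s * np.exp(m.beta * m.gamma_tilde_s * A_m)
            direct = ks_of_costheta(
                costheta, make_model(K_s0=K_s0, gamma=m.gamma), geo)
            via_kv = ks_kv_correlation(K_v, costheta, m)
            assert via_kv == pytest.approx(direct, rel=1e-10)
            assert area_from_kv(K_v, m) == pytest.approx(A_m, rel=1e-10)

    def test_log_slope_decreases_with_costheta(self):
        m = make_model()
        K_v = np.array([1.0, 10.0, 100.0])
        slopes = []
        for costheta in [-0.8, -0.3, 0.2, 0.7]:
            ks = ks_kv_correlation(K_v, costheta, m)
            slope = np.polyfit(np.log(K_v), np.log(ks), 1)[0]
            slopes.append(slope)
        assert np.all(np.diff(slopes) < 0)

    def test_kv_below_prefactor_rejected(self):
        m = make_model(b_v=0.5)
        with pytest.raises(ValueError, match="non-positive molecular area"):
            ks_kv_correlation(0.4, 0.0, m)
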