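"""Surface-tension reduction: closed form, linear limit, Gibbs-path oracle."""

import numpy as np
import pytest
from scipy.integrate import quad

from surfwet.isotherms import LangmuirFit
from surfwet.synthetic import make_isotherm_series
from surfwet.tension import (TensionModel, dgamma_linear, dgamma_of_c,
                             dgamma_of_gamma)
from surfwet.units import kT, molar_to_nm3, nm3_to_molar


def gibbs_path_oracle(gamma_target, gamma_inf, k_c, dG, T=300.0):
    """Independent quadrature of dgamma = -Gamma dmu along the Langmuir curve
    with the constant-KB chemical potential (d beta mu = dc / [c(1 + dG c)]).
    Concentrations in nm^-3."""
    c_end = gamma_target / (k_c * (gamma_inf - gamma_target))

    def integrand(c):
        return gamma_inf * k_c / ((1 + k_c * c) * (1 + dG * c))

    val, _ = quad(integrand, 0.0, c_end, epsabs=1e-12, epsrel=1e-12)
    return -kT(T) * val


def model_from(gamma_inf, k_c, dG, T=300.0):
    K = k_c * gamma_inf
    xi = 1.0 - gamma_inf * dG / K
    return TensionModel(gamma_inf=gamma_inf, xi=xi, T=T)


class TestClosedForm:
    def test_zero_adsorption(self):
        m = TensionModel(gamma_inf=5.0, xi=0.9)
        res = dgamma_of_gamma(0.0, m)
        assert res.dgamma == 0.0 and res.surface_pressure == 0.0

    def test_beyond_saturation_rejected(self):
        m = TensionModel(gamma_inf=5.0, xi=0.9)
        with pytest.raises(ValueError, match="saturation"):
            dgamma_of_gamma(5.0, m)

    def test_matches_gibbs_path_quadrature(self):
        gamma_inf, k_c, dG = 5.0, 2.0, 0.8
        m = model_from(gamma_inf, k_c, dG)
        for frac in [0.01, 0.1, 0.5, 0.9]:
            g = frac * gamma_inf
            closed = dgamma_of_gamma(g, m).dgamma
            oracle = gibbs_path_oracle(g, gamma_inf, k_c, dG)
            assert closed == pytest.approx(oracle, rel=1e-8)

    def test_szyszkowski_at_xi_one(self):
        m = TensionModel(gamma_inf=4.0, xi=1.0, T=300.0)
        g = 2.0
        expected = kT(300.0) * 4.0 * np.log(1 - g / 4.0)
        assert dgamma_of_gamma(g, m).dgamma == pytest.approx(expected)

    def test_monotone_decreasing_in_gamma(self):
        m = TensionModel(gamma_inf=5.0, xi=0.7)
        g = np.linspace(0, 4.99, 200)
        dg = dgamma_of_gamma(g, m).dgamma
        assert np.all(np.diff(dg) < 0)

    def test_finite_saturation_value_for_xi_below_one(self):
        m = TensionModel(gamma_inf=5.0, xi=0.8)
        near = dgamma_of_gamma(5.0 * (1 - 1e-12), m).dgamma
        limit = kT(300.0) * 5.0 / 0.8 * np.log(1 - 0.8)
        assert near == pytest.approx(limit, rel=1e-9)

    def test_surface_pressure_sign(self):
        m = TensionModel(gamma_inf=5.0, xi=0.9)
        res = dgamma_of_gamma(2.0, m)
        assert res.dgamma < 0 < res.surface_pressure
        assert res.surface_pressure == -res.dgamma


class TestLinearLaw:
    def test_zero(self):
        m = TensionModel(gamma_inf=5.0, xi=1.0)
        assert dgamma_linear(0.0, m).dgamma == 0.0

    def test_thermal_energy_arithmetic(self):
        m = TensionModel(gamma_inf=5.0, xi=1.0, T=300.0)
        res = dgamma_linear(0.5, m)
        assert res.dgamma == pytest.approx(-4.14 * 0.5, abs=2e-3)
        assert res.dgamma == pytest.approx(-2.07, abs=2e-3)

    def test_ratio_to_closed_form_tends_to_one(self):
        m = TensionModel(gamma_inf=5.0, xi=0.7)
        for g in [1e-2, 1e-4, 1e-6]:
            ratio = dgamma_of_gamma(g, m).dgamma / dgamma_linear(g, m).dgamma
            assert ratio == pytest.approx(1.0, abs=5 * g)

    def test_validity_flag(self):
        m = TensionModel(gamma_inf=5.0, xi=0.8)
        assert dgamma_linear(0.1, m).linear_ok
        assert not dgamma_linear(0.9 * 5.0 / 0.8, m).linear_ok

    def test_second_order_coefficient(self):
        # (closed - linear)/Gamma^2 -> -kT xi / (2 Gamma_inf) as Gamma -> 0
        gamma_inf, xi = 5.0, 0.7
        m = TensionModel(gamma_inf=gamma_inf, xi=xi)
        target = -kT(300.0) * xi / (2 * gamma_inf)
        g = np.array([1e-2, 1e-3, 1e-4])
        coeff = (dgamma_of_gamma(g, m).dgamma
                 - dgamma_linear(g, m).dgamma) / g**2
        err = np.abs(coeff - target) / abs(target)
        assert err[-1] < 1e-4
        assert np.all(np.diff(err) < 0)


class TestDgammaOfC:
    @staticmethod
    def fit(k_c=2.0, gamma_inf=5.0):
        return LangmuirFit(k_c=k_c, gamma_inf=gamma_inf,
                           covariance=np.eye(2), fit_window=(0, 1))

    def test_zero_concentration(self):
        m = TensionModel(gamma_inf=5.0, xi=0.9)
        assert dgamma_of_c(0.0, self.fit(), m).dgamma == 0.0

    def test_low_concentration_slope_is_minus_kT_K(self):
        fit = self.fit(k_c=2.0, gamma_inf=5.0)
        m = model_from(5.0, 2.0, dG=0.3)
        h = 1e-8
        slope = dgamma_of_c(h, fit, m).dgamma / molar_to_nm3(h)
        assert slope == pytest.approx(-kT(300.0) * fit.K, rel=1e-6)

    def test_saturation_plateau(self):
        fit = self.fit(k_c=2.0, gamma_inf=5.0)
        m = TensionModel(gamma_inf=5.0, xi=0.8)
        big = dgamma_of_c(1e5, fit, m).dgamma
        limit = kT(300.0) * 5.0 / 0.8 * np.log(1 - 0.8)
        assert big == pytest.approx(limit, rel=1e-4)

    def test_monotone_nonincreasing_in_c(self):
        fit = self.fit()
        m = TensionModel(gamma_inf=5.0, xi=0.9)
        c = np.linspace(0, 2, 100)
        dg = dgamma_of_c(c, fit, m).dgamma
        assert np.all(np.diff(dg) < 0)

    def test_inconsistent_gamma_inf_rejected(self):
        m = TensionModel(gamma_inf=4.0, xi=0.9)
        with pytest.raises(ValueError, match="Gamma_inf"):
            dgamma_of_c(0.1, self.fit(gamma_inf=5.0), m)

    def test_beyond_model_flag_for_absolute_tension(self):
        fit = self.fit(k_c=2.0, gamma_inf=5.0)
        m = TensionModel(gamma_inf=5.0, xi=1.0, gamma0=5.0)  # weak interface
        res = dgamma_of_c(10.0, fit, m)
        assert res.beyond_model
        ok = dgamma_of_c(1e-3, fit, m)
        assert not ok.beyond_model


def test_pipeline_composition_matches_generator_truth():
    """Generated isotherm -> fit -> tension closes on the analytic curve."""
    from surfwet.isotherms import fit_langmuir

    k_c, gamma_inf, dG = 3.0, 5.0, 0.5
    series = make_isotherm_series(k_c, gamma_inf,
                                  np.geomspace(0.01, 1.0, 8), 0, 0)
    fit = fit_langmuir(series)
    m = model_from(gamma_inf, k_c, dG)
    m = TensionModel(gamma_inf=fit.gamma_inf, xi=m.xi)
    c0 = 0.2
    gamma = fit.predict(c0)
    closed = dgamma_of_c(c0, fit, m).dgamma
    oracle = gibbs_path_oracle(gamma, fit.gamma_inf, fit.k_c, dG)
    assert closed == pytest.approx(oracle, rel=1e-5)
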