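"""Interface location and surface-excess integration."""

import numpy as np
import pytest

from surfwet.profiles import (DensityProfile, excess_adsorption, find_bulk,
                              gibbs_dividing_surface, infer_liquid_side,
                              measure_adsorption, solid_boundary)
from surfwet.synthetic import SurfactantTruth, make_slab_profiles
from surfwet.units import molar_to_nm3


def profile(z, d, **kw):
    return DensityProfile(np.asarray(z), np.asarray(d), **kw)


def grid(n=501, L=10.0):
    return np.linspace(0.0, L, n)


class TestDensityProfile:
    def test_rejects_nonuniform_grid(self):
        z = np.array([0.0, 0.1, 0.25, 0.3, 0.4])
        with pytest.raises(ValueError, match="uniform"):
            profile(z, np.ones_like(z))

    def test_rejects_negative_density(self):
        z = grid(11)
        with pytest.raises(ValueError, match="non-negative"):
            profile(z, -np.ones_like(z))


class TestFindBulk:
    def test_uniform_profile_gives_full_window(self):
        z = grid()
        win = find_bulk(profile(z, np.full_like(z, 2.5)))
        assert win.z_lo == z[0] and win.z_hi == z[-1]
        assert win.c_bulk == pytest.approx(2.5)

    def test_slab_with_peak_recovers_bulk_concentration(self, slab_spec):
        truth = SurfactantTruth(c0=0.2, gamma_true=1.0, peak_width=0.3)
        _, surf = make_slab_profiles(slab_spec, truth)
        win = find_bulk(surf)
        assert win.c_bulk == pytest.approx(molar_to_nm3(0.2), rel=5e-3)
        # window must exclude the interfacial peak region around z = 5 nm
        assert win.z_lo > slab_spec.edge + 0.5

    def test_monotone_ramp_has_no_plateau(self):
        z = grid()
        with pytest.raises(ValueError, match="no bulk plateau"):
            find_bulk(profile(z, 1.0 + z))


class TestGibbsDividingSurface:
    def test_step_profile(self):
        z = grid()
        d = np.where(z < 4.0, 33.0, 0.0)  # liquid below z* = 4
        z0 = gibbs_dividing_surface(profile(z, d), c_bulk=33.0,
                                    liquid_side="lower")
        assert z0 == pytest.approx(4.0, abs=2e-2)

    def test_linear_ramp_midpoint(self):
        z = grid(1001)
        z1, z2 = 4.0, 6.0
        d = np.interp(z, [0, z1, z2, 10], [33.0, 33.0, 0.0, 0.0])
        z0 = gibbs_dividing_surface(profile(z, d), c_bulk=33.0,
                                    liquid_side="lower")
        assert z0 == pytest.approx((z1 + z2) / 2.0, abs=1e-6)

    def test_tanh_edge_center(self, clean_profiles):
        water, _ = clean_profiles
        z0 = gibbs_dividing_surface(water)
        assert z0 == pytest.approx(5.0, abs=1e-6)

    def test_water_self_consistency(self, clean_profiles):
        # integrating the water excess against its own dividing surface is zero
        water, _ = clean_profiles
        z0 = gibbs_dividing_surface(water)
        resid = excess_adsorption(water, z0, c_bulk=33.0, dz=water.dz,
                                  liquid_side="upper")
        assert abs(resid) < 1e-9

    def test_nondecaying_tail_rejected(self):
        z = grid()
        with pytest.raises(ValueError, match="decay"):
            gibbs_dividing_surface(profile(z, np.full_like(z, 33.0)),
                                   c_bulk=33.0, liquid_side="upper")


class TestSolidBoundary:
    def test_gaussian_half_height(self):
        z = grid(2001)
        d = np.exp(-0.5 * ((z - 1.0) / 0.1) ** 2)
        z_s = solid_boundary(profile(z, d), water_side="upper")
        assert z_s == pytest.approx(1.0 + 0.1 * np.sqrt(2 * np.log(2)),
                                    abs=1e-3)

    def test_rectangular_peak_edge(self):
        z = grid(1001)
        d = np.where((z >= 0.9) & (z <= 1.1), 4.3, 0.0)
        z_s = solid_boundary(profile(z, d), water_side="upper")
        assert z_s == pytest.approx(1.1, abs=z[1] - z[0])

    def test_flat_profile_rejected(self):
        z = grid()
        with pytest.raises(ValueError, match="flat"):
            solid_boundary(profile(z, np.zeros_like(z)))

    def test_multimodal_flank_lists_candidates(self):
        z = grid(2001)
        d = (np.exp(-0.5 * ((z - 1.0) / 0.1) ** 2)
             + 0.9 * np.exp(-0.5 * ((z - 2.0) / 0.1) ** 2))
        with pytest.raises(ValueError, match="ambiguous"):
            solid_boundary(profile(z, d), water_side="upper")


class TestExcessAdsorption:
    def test_pure_bulk_step_has_zero_excess(self):
        z = grid(1001)
        c_bulk = molar_to_nm3(0.1)
        d = np.where(z > 5.0, c_bulk, 0.0)
        gamma = excess_adsorption(profile(z, d), z0=5.0, c_bulk=c_bulk,
                                  liquid_side="upper")
        assert gamma == pytest.approx(0.0, abs=5e-3)

    def test_gaussian_peak_area_recovered(self, clean_profiles):
        water, surf = clean_profiles
        z0 = gibbs_dividing_surface(water)
        gamma = excess_adsorption(surf, z0, c_bulk=molar_to_nm3(0.1),
                                  liquid_side="upper")
        assert gamma == pytest.approx(1.0, abs=0.01)

    def test_quadrature_convergence(self, clean_profiles):
        water, surf = clean_profiles
        z0 = gibbs_dividing_surface(water)
        c_bulk = molar_to_nm3(0.1)
        g1 = excess_adsorption(surf, z0, c_bulk, dz=0.1, liquid_side="upper")
        g2 = excess_adsorption(surf, z0, c_bulk, dz=0.05, liquid_side="upper")
        assert abs(g2 - g1) / abs(g1) < 5e-3

    def test_endpoints_inside_interfacial_region_rejected(self, clean_profiles):
        water, surf = clean_profiles
        with pytest.raises(ValueError, match="endpoints"):
            excess_adsorption(surf, z0=9.5, c_bulk=0.06, liquid_side="upper")

    def test_translation_invariance(self, slab_spec, clean_profiles):
        water, surf = clean_profiles
        z0 = gibbs_dividing_surface(water)
        gamma = excess_adsorption(surf, z0, molar_to_nm3(0.1),
                                  liquid_side="upper")
        shifted = DensityProfile(surf.z + 3.7, surf.density,
                                 species=surf.species)
        gamma_shifted = excess_adsorption(shifted, z0 + 3.7, molar_to_nm3(0.1),
                                          liquid_side="upper")
        assert gamma_shifted == pytest.approx(gamma, rel=1e-12)

    def test_two_sided_slab_interfaces_agree(self, slab_spec):
        from dataclasses import replace

        spec = replace(slab_spec, slab_center=5.0)
        truth = SurfactantTruth(c0=0.1, gamma_true=0.8, peak_width=0.3)
        water, surf = make_slab_profiles(spec, truth, two_sided=True)
        c_bulk = molar_to_nm3(0.1)
        mid = len(water.z) // 2
        lo_w = DensityProfile(water.z[: mid + 1], water.density[: mid + 1])
        hi_w = DensityProfile(water.z[mid:], water.density[mid:])
        lo_s = DensityProfile(surf.z[: mid + 1], surf.density[: mid + 1])
        hi_s = DensityProfile(surf.z[mid:], surf.density[mid:])
        g_lo = excess_adsorption(
            lo_s, gibbs_dividing_surface(lo_w, liquid_side="upper"),
            c_bulk, liquid_side="upper")
        g_hi = excess_adsorption(
            hi_s, gibbs_dividing_surface(hi_w, liquid_side="lower"),
            c_bulk, liquid_side="lower")
        assert g_lo == pytest.approx(g_hi, rel=1e-6)
        assert g_lo == pytest.approx(0.8, abs=0.01)


def test_measure_adsorption_end_to_end(slab_spec):
    truth = SurfactantTruth(c0=0.15, gamma_true=1.3, peak_width=0.25)
    water, surf = make_slab_profiles(slab_spec, truth)
    frame, gamma = measure_adsorption(water, surf)
    assert infer_liquid_side(water) == "upper"
    assert frame.z0 == pytest.approx(5.0, abs=1e-6)
    assert frame.c_bulk == pytest.approx(molar_to_nm3(0.15), rel=5e-3)
    assert gamma == pytest.approx(1.3, abs=0.015)


def test_profile_file_roundtrip_with_xvg_metadata(tmp_path, clean_profiles):
    water, _ = clean_profiles
    path = tmp_path / "water.dat"
    water.to_file(path)
    text = path.read_text()
    path.write_text('@ title "density"\n@ xaxis label "z"\n' + text)
    back = DensityProfile.from_file(path)
    np.testing.assert_allclose(back.z, water.z, atol=1e-9)
    np.testing.assert_allclose(back.density, water.density, rtol=1e-9)
    assert back.species == "water"
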