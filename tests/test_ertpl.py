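"""Equivalent transmittance and equivalent path length of hemispherical data."""

import numpy as np
import pytest

import hemisif as hs

H = 20.0


def bowl_field(amplitude: float) -> hs.DirectionalField:
    """Azimuth-uniform field rising with zenith as 1 + a sin^2(theta)."""
    g = hs.AngularGrid.regular()
    profile = 1.0 + amplitude * np.sin(np.radians(g.zenith_centers)) ** 2
    return hs.DirectionalField(np.repeat(profile[:, None], g.n_azimuth, axis=1), g)


def beer_lambert_t(model: hs.TransmittanceModel, height: float = H):
    def t(theta):
        return model.transmittance(
            height / np.cos(np.radians(np.asarray(theta, dtype=float)))
        )

    return t


class TestHemisphericalIrradiance:
    def test_isotropic_without_absorption_gives_pi(self, iso_field):
        assert hs.hemispherical_irradiance(iso_field) == pytest.approx(np.pi, rel=1e-12)

    def test_zero_field_integrates_to_zero(self):
        g = hs.AngularGrid.regular()
        f = hs.DirectionalField(np.zeros((g.n_zenith, g.n_azimuth)), g)
        assert hs.hemispherical_irradiance(f) == 0.0

    def test_matches_dense_quadrature_oracle(self, iso_field, o2a_constant_model):
        """Ring Gauss-Legendre agrees with a 0.001-deg trapezoid reference."""
        t = beer_lambert_t(o2a_constant_model)
        e = hs.hemispherical_irradiance(iso_field, t)
        step = 0.001
        th = np.radians(np.arange(0.0, 90.0 + step / 2, step))
        dense = 2 * np.pi * np.trapezoid(
            np.exp(-o2a_constant_model.kappa * H / np.cos(th)) * np.cos(th) * np.sin(th),
            th,
        )
        assert e == pytest.approx(dense, rel=1e-8)

    def test_transmittance_above_one_rejected(self, iso_field):
        with pytest.raises(ValueError):
            hs.hemispherical_irradiance(iso_field, lambda th: np.full(np.shape(th), 1.5))


class TestEquivalentTransmittance:
    def test_unity_transmittance(self, iso_field):
        assert hs.equivalent_transmittance(
            iso_field, lambda th: np.ones(np.shape(th))
        ) == pytest.approx(1.0, rel=1e-12)

    def test_path_linear_transmittance_closed_form(self, iso_field):
        """T = a + b * H sec(theta) integrates to a + 2bH for isotropic fields."""
        a, b = 1.0, -0.001

        def t(theta):
            return a + b * H / np.cos(np.radians(np.asarray(theta, dtype=float)))

        assert hs.equivalent_transmittance(iso_field, t) == pytest.approx(
            a + 2 * b * H, abs=1e-12
        )

    def test_zero_field_rejected(self):
        g = hs.AngularGrid.regular()
        f = hs.DirectionalField(np.zeros((g.n_zenith, g.n_azimuth)), g)
        with pytest.raises(ValueError):
            hs.equivalent_transmittance(f, lambda th: np.ones(np.shape(th)))

    def test_decreases_with_extinction_and_height(self, iso_field):
        k0 = hs.DEFAULT_KAPPA_O2A

        def tbar(kappa, height):
            m = hs.TransmittanceModel.constant(kappa)
            return hs.equivalent_transmittance(iso_field, beer_lambert_t(m, height))

        assert tbar(2 * k0, 20.0) < tbar(k0, 20.0) < 1.0
        assert tbar(k0, 40.0) < tbar(k0, 20.0)


class TestClosedForm:
    def test_twice_sensor_height(self):
        assert hs.ertpl_closed_form(20.0) == 40.0
        assert hs.ertpl_closed_form(1.0) == 2.0

    def test_quadrature_agrees_with_closed_form(self):
        """0.01-deg trapezoid of 2 H sec cos sin matches 2H to 1e-6 relative."""
        assert hs.mean_slant_path(20.0, zenith_step=0.01) == pytest.approx(
            40.0, rel=1e-6
        )

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError):
            hs.ertpl_closed_form(0.0)


class TestErtplFromFields:
    def test_isotropic_with_exactly_linear_transmittance_gives_2h(self, iso_field):
        """The closed-form identity: quadrature + line inversion recover 2H."""
        a, b = 1.0, -0.001

        def t(theta):
            return a + b * H / np.cos(np.radians(np.asarray(theta, dtype=float)))

        tbar = hs.equivalent_transmittance(iso_field, t)
        ertpl = (tbar - a) / b
        assert ertpl == pytest.approx(2 * H, abs=1e-9)

    def test_isotropic_beer_lambert_ratio_below_two(self, iso_field, o2a_constant_model):
        res = hs.ertpl_from_fields(iso_field, o2a_constant_model, H)
        assert 1.8 < res.ertpl_ratio < 2.0
        assert res.ertpl >= H

    def test_bowl_anisotropy_raises_ratio_toward_two(self, o2a_constant_model):
        """Longer slant paths gain weight in a bowl field, opposing the
        transmittance-curvature shortening; at the default extinction the
        combination stays below the closed-form 2H."""
        iso = hs.ertpl_from_fields(
            hs.DirectionalField.isotropic(1.0), o2a_constant_model, H
        ).ertpl_ratio
        ratios = [
            hs.ertpl_from_fields(bowl_field(a), o2a_constant_model, H).ertpl_ratio
            for a in (0.10, 0.25, 0.35)
        ]
        assert all(r > iso for r in ratios)
        assert all(np.diff(ratios) > 0)
        assert all(r < 2.0 for r in ratios)

    def test_ratio_approaches_two_as_extinction_vanishes(self, iso_field):
        """For isotropic scenes the weak-absorption limit is the closed form."""
        k0 = hs.DEFAULT_KAPPA_O2A
        gaps = []
        for scale in (1.0, 0.5, 0.1, 0.01):
            m = hs.TransmittanceModel.constant(k0 * scale)
            gaps.append(2.0 - hs.ertpl_from_fields(iso_field, m, H).ertpl_ratio)
        assert all(g > 0 for g in gaps)
        assert all(np.diff(gaps) < 0)

    def test_monotone_in_extinction_for_bowl_fields(self):
        k0 = hs.DEFAULT_KAPPA_O2A
        f = bowl_field(0.25)
        ratios = [
            hs.ertpl_from_fields(f, hs.TransmittanceModel.constant(k0 * s), H).ertpl_ratio
            for s in (1.0, 0.5, 0.1)
        ]
        assert all(np.diff(ratios) > 0)

    def test_absorption_free_model_is_degenerate(self, iso_field):
        res = hs.ertpl_from_fields(iso_field, hs.TransmittanceModel.constant(0.0), H)
        assert res.degenerate
        assert np.isnan(res.ertpl)
        assert res.equivalent_transmittance == pytest.approx(1.0, rel=1e-12)

    def test_spectral_field_requires_wavelength(self, o2a_spectral_model):
        g = hs.AngularGrid.regular()
        wl = np.array([760.0, 761.1])
        f = hs.DirectionalField(np.ones((g.n_zenith, g.n_azimuth, 2)), g, wl)
        with pytest.raises(ValueError):
            hs.ertpl_from_fields(f, o2a_spectral_model, H)
        res = hs.ertpl_from_fields(f, o2a_spectral_model, H, wavelength=761.1)
        assert 1.8 < res.ertpl_ratio < 2.0


class TestRoundTrip:
    def test_propagate_then_correct_with_exact_tbar(self, o2a_constant_model):
        """Dividing Ecos by the exactly computed Tbar restores E0 to 1e-12."""
        f = bowl_field(0.3)
        t = beer_lambert_t(o2a_constant_model)
        e0 = hs.hemispherical_irradiance(f)
        ecos = hs.hemispherical_irradiance(f, t)
        tbar = hs.equivalent_transmittance(f, t)
        assert ecos / tbar == pytest.approx(e0, rel=1e-12)
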