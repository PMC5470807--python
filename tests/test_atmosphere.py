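"""Beer-Lambert transmittance, linearity over tower paths, and correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemisif as hs
from hemisif.atmosphere import DEFAULT_KAPPA_O2A


class TestTransmittanceModel:
    def test_calibration_anchor(self, o2a_constant_model):
        assert o2a_constant_model.transmittance(37.7) == pytest.approx(0.924, abs=1e-12)
        assert o2a_constant_model.kappa == pytest.approx(DEFAULT_KAPPA_O2A, rel=1e-12)

    def test_zero_path_is_unity(self, o2a_constant_model):
        assert o2a_constant_model.transmittance(0.0) == 1.0

    def test_double_path_squares(self, o2a_constant_model):
        assert o2a_constant_model.transmittance(75.4) == pytest.approx(0.924**2, abs=1e-12)

    @settings(deadline=None)
    @given(
        st.floats(min_value=0.0, max_value=500.0),
        st.floats(min_value=0.0, max_value=500.0),
    )
    def test_multiplicative_in_path(self, a, b):
        m = hs.TransmittanceModel.from_calibration(0.924, 37.7)
        assert m.transmittance(a + b) == pytest.approx(
            m.transmittance(a) * m.transmittance(b), rel=1e-12
        )

    def test_negative_path_rejected(self, o2a_constant_model):
        with pytest.raises(ValueError):
            o2a_constant_model.transmittance(-1.0)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            hs.TransmittanceModel.constant(-1e-3)

    def test_spectral_line_peaks_at_center_and_vanishes_at_shoulders(
        self, o2a_spectral_model
    ):
        k_in = o2a_spectral_model.kappa_at(761.1)
        assert k_in == pytest.approx(DEFAULT_KAPPA_O2A, rel=1e-9)
        assert o2a_spectral_model.kappa_at(758.7) < 1e-3 * k_in
        assert o2a_spectral_model.kappa_at(770.1) < 1e-9 * k_in

    def test_spectral_evaluation_broadcasts_over_wavelength(self, o2a_spectral_model):
        wl = np.array([758.7, 761.1, 770.1])
        t = o2a_spectral_model.transmittance(40.0, wl)
        assert t.shape == (3,)
        assert t[1] < t[0] <= t[2]


class TestLinearPathFit:
    def test_r_squared_above_099_on_tower_paths(self, o2a_constant_model):
        """T vs path is near-linear over 20-65 m at the O2-A extinction."""
        fit = hs.fit_linear_T(o2a_constant_model, None, np.arange(20.0, 66.0, 1.0))
        assert fit.r_squared > 0.99
        assert fit.slope < 0

    def test_residuals_match_direct_recomputation(self, o2a_constant_model):
        paths = np.arange(20.0, 66.0, 1.0)
        fit = hs.fit_linear_T(o2a_constant_model, None, paths)
        res = o2a_constant_model.transmittance(paths) - fit.predict(paths)
        expected = np.exp(-o2a_constant_model.kappa * paths) - (
            fit.intercept + fit.slope * paths
        )
        assert np.allclose(res, expected, atol=1e-12)

    def test_absorption_free_fit_is_flagged_perfect(self):
        fit = hs.fit_linear_T(hs.TransmittanceModel.constant(0.0), None, [20.0, 40.0, 60.0])
        assert fit.degenerate
        assert fit.slope == 0.0
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == 1.0
        with pytest.raises(ValueError):
            fit.invert(0.95)

    def test_too_few_paths_rejected(self, o2a_constant_model):
        with pytest.raises(ValueError):
            hs.fit_linear_T(o2a_constant_model, None, [20.0, 20.0, 20.0])
        with pytest.raises(ValueError):
            hs.fit_linear_T(o2a_constant_model, None, [20.0, 30.0])

    def test_inversion_warns_on_extrapolation(self, o2a_constant_model):
        fit = hs.fit_linear_T(o2a_constant_model, None, np.arange(20.0, 66.0, 1.0))
        with pytest.warns(UserWarning, match="extrapolates"):
            fit.invert(1.0)


class TestRadianceCorrection:
    def test_exact_inverse_of_attenuation(self):
        assert hs.correct_radiance(10.0 * 0.924, 0.924) == pytest.approx(10.0, rel=1e-12)

    def test_unity_transmittance_is_identity(self):
        assert hs.correct_radiance(10.0, 1.0) == 10.0

    def test_round_trip_with_surface_coupling(self):
        coupling = hs.SurfaceCoupling(rho=0.4, spherical_albedo=0.1, path_radiance=0.2)
        L0 = 57.3
        LH = hs.propagate_radiance(L0, 0.9, coupling)
        assert hs.correct_radiance(LH, 0.9, coupling) == pytest.approx(L0, rel=1e-12)

    def test_invalid_transmittance_rejected(self):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                hs.correct_radiance(10.0, bad)

    def test_overcorrection_warns(self):
        with pytest.warns(UserWarning, match="over-correction"):
            hs.correct_radiance(0.1, 0.9, hs.SurfaceCoupling(path_radiance=0.5))

    def test_coupling_validation(self):
        with pytest.raises(ValueError):
            hs.SurfaceCoupling(rho=1.0, spherical_albedo=1.0)
        with pytest.raises(ValueError):
            hs.SurfaceCoupling(path_radiance=-0.1)


class TestHemisphericalCorrection:
    def test_absorption_free_identity(self):
        m = hs.TransmittanceModel.constant(0.0)
        assert hs.correct_hemispherical_irradiance(5.0, 20.0, m) == 5.0

    def test_divides_by_equivalent_path_transmittance(self, o2a_constant_model):
        out = hs.correct_hemispherical_irradiance(1.0, 20.0, o2a_constant_model)
        assert out == pytest.approx(1.0 / o2a_constant_model.transmittance(40.0), rel=1e-12)

    def test_invalid_ratio_rejected(self, o2a_constant_model):
        with pytest.raises(ValueError):
            hs.correct_hemispherical_irradiance(1.0, 20.0, o2a_constant_model, ertpl_ratio=0.0)

    def test_at_sensor_irradiance_never_exceeds_toc(self, o2a_constant_model, iso_field):
        """Energy: attenuation can only reduce hemispherical irradiance."""
        def t(theta):
            return o2a_constant_model.transmittance(
                20.0 / np.cos(np.radians(np.asarray(theta, dtype=float)))
            )

        e0 = hs.hemispherical_irradiance(iso_field)
        ecos = hs.hemispherical_irradiance(iso_field, t)
        assert ecos <= e0
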