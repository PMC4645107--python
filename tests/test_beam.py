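import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiphase import defaults
from hiphase.beam import (
    BeamModel,
    FluenceQuadrature,
    GaussianComponent,
    SpatialProfile,
    TemporalProfile,
    attenuator_transmission,
    average_dose,
    fluence_quadrature,
    fluence_ratio_to_saturation,
    peak_fluence,
    photons_per_pulse,
)
from hiphase.errors import (
    ConfigError,
    DomainError,
    GeometryError,
    TableLookupError,
    UnsupportedProfileError,
)

from .conftest import make_beam


class TestPhotonsPerPulse:
    def test_reference_count(self, hf_beam):
        # 1.6 mJ * 0.3 / (8.48 keV) = 3.53e11 photons
        assert photons_per_pulse(hf_beam) == pytest.approx(3.533e11, rel=1e-3)

    def test_attenuation_is_linear(self, hf_beam, lf_beam):
        assert photons_per_pulse(lf_beam) == pytest.approx(
            photons_per_pulse(hf_beam) * defaults.LF_ATTENUATION
        )

    def test_zero_pulse_energy_rejected(self):
        with pytest.raises(DomainError):
            make_beam().__class__(
                photon_energy_keV=8.48,
                pulse_energy_mJ=0.0,
                optics_transmission=0.3,
                attenuation=1.0,
                spatial=SpatialProfile.gaussian(0.2),
                temporal=TemporalProfile(40.0),
            )


class TestPeakFluence:
    def test_reference_hf_peak(self, hf_beam):
        peak = peak_fluence(photons_per_pulse(hf_beam), hf_beam.spatial)
        assert peak == pytest.approx(7.8e12, rel=0.01)

    def test_reference_lf_peak(self, lf_beam):
        peak = peak_fluence(photons_per_pulse(lf_beam), lf_beam.spatial)
        assert peak == pytest.approx(0.0173 * 7.795e12, rel=0.01)

    def test_doubling_fwhm_quarters_peak(self):
        n = 1e11
        p1 = peak_fluence(n, SpatialProfile.gaussian(0.2))
        p2 = peak_fluence(n, SpatialProfile.gaussian(0.4))
        assert p1 == pytest.approx(4 * p2)

    def test_linear_in_photons(self):
        spatial = SpatialProfile.gaussian(0.2)
        assert peak_fluence(2e11, spatial) == pytest.approx(
            2 * peak_fluence(1e11, spatial)
        )

    def test_double_gaussian_peak_is_component_sum(self):
        n = 1e11
        dg = SpatialProfile.double_gaussian()
        parts = sum(
            c.photon_fraction * n / (2 * math.pi * c.sigma_um**2)
            for c in dg.components
        )
        assert peak_fluence(n, dg) == pytest.approx(parts)

    def test_point_profile_unsupported(self):
        with pytest.raises(UnsupportedProfileError):
            peak_fluence(1e11, SpatialProfile.point(1e11))


class TestFluenceQuadrature:
    def test_weights_sum_to_one_and_mean_is_half_peak(self):
        n = 1e11
        spatial = SpatialProfile.gaussian(0.2)
        quad = fluence_quadrature(spatial, n, n_nodes=200)
        peak = peak_fluence(n, spatial)
        assert quad.weights.sum() == pytest.approx(1.0)
        assert quad.mean_fluence == pytest.approx(peak / 2, rel=1e-6)

    def test_gaussian_photon_weighted_fluence_is_uniform_brute_force(self):
        # independent oracle: integrate F(r) dA over a fine 2-D grid and
        # build the photon-weighted empirical CDF of the local fluence
        n_photons = 1e11
        fwhm = 0.2
        sigma = fwhm / math.sqrt(8 * math.log(2))
        peak = n_photons / (2 * math.pi * sigma**2)
        half = 6 * sigma
        ax = np.linspace(-half, half, 1201)
        dx = ax[1] - ax[0]
        xx, yy = np.meshgrid(ax, ax)
        fl = peak * np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
        weights = (fl * dx * dx / n_photons).ravel()
        order = np.argsort(fl.ravel())
        cdf = np.cumsum(weights[order])
        fractions = fl.ravel()[order] / peak
        # photon-weighted CDF of F/Fpeak should be the identity
        sel = slice(None, None, 997)
        assert np.allclose(cdf[sel], fractions[sel], atol=2e-3)
        # and the quadrature encodes exactly that uniform law
        quad = fluence_quadrature(SpatialProfile.gaussian(fwhm), n_photons, 64)
        assert np.allclose(np.sort(quad.nodes) / peak,
                           (np.arange(64) + 0.5) / 64)

    def test_point_profile_single_node(self):
        quad = fluence_quadrature(SpatialProfile.point(3.3e10), 1e11)
        assert quad.nodes.tolist() == [3.3e10]
        assert quad.weights.tolist() == [1.0]

    def test_double_gaussian_component_weights(self):
        quad = fluence_quadrature(SpatialProfile.double_gaussian(), 1e11, 16)
        assert quad.weights[:16].sum() == pytest.approx(0.5)
        assert quad.weights[16:].sum() == pytest.approx(0.5)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ConfigError):
            fluence_quadrature(SpatialProfile.gaussian(0.2), 1e11, n_nodes=1)


class TestAverageDose:
    def test_lf_hf_ratio_is_attenuation(self):
        hf = average_dose(7.8e12, 8.48)
        lf = average_dose(7.8e12 * 0.0173, 8.48)
        assert lf / hf == pytest.approx(0.0173)

    def test_zero_fluence(self):
        assert average_dose(0.0, 8.48) == 0.0

    def test_reference_scale(self):
        # order 1e9 Gy; agreement with the reported 1.27 GGy only within
        # a factor of 2.5 (averaging convention is an estimate)
        dose = average_dose(7.8e12, 8.48, "protein")
        assert 1e9 < dose < 1e10
        assert 1 / 2.5 < dose / 1.27e9 < 2.5

    def test_missing_medium(self):
        with pytest.raises(TableLookupError):
            average_dose(1e11, 8.48, "kryptonite")

    def test_conventions(self):
        assert average_dose(1e12, 8.48, convention="at_fluence") == pytest.approx(
            2 * average_dose(1e12, 8.48, convention="gaussian_mean")
        )


class TestAttenuatorTransmission:
    def test_zero_thickness(self):
        assert attenuator_transmission(0.0, "Si", 8.48) == 1.0

    def test_angle_closed_form(self):
        t0 = attenuator_transmission(240.0, "Si", 8.48, 0.0)
        t30 = attenuator_transmission(240.0, "Si", 8.48, math.pi / 6)
        assert t30 == pytest.approx(t0 ** (1 / math.cos(math.pi / 6)))

    def test_si_240um_from_shipped_table(self):
        # exp(-(mu/rho) * rho * t) with the tabulated Si coefficients
        mu_rho = math.exp(
            np.interp(
                math.log(8.48),
                np.log([6.0, 8.0, 10.0, 12.0]),
                np.log([147.0, 64.7, 33.9, 20.0]),
            )
        )
        expected = math.exp(-mu_rho * 2.33 * 240e-4)
        assert attenuator_transmission(240.0, "Si", 8.48) == pytest.approx(expected)

    def test_invalid_angle(self):
        with pytest.raises(GeometryError):
            attenuator_transmission(240.0, "Si", 8.48, math.pi / 2)

    @given(
        thickness=st.floats(1.0, 500.0),
        two_theta=st.floats(0.0, 1.4),
    )
    @settings(max_examples=25, deadline=None)
    def test_bounded_and_decreasing(self, thickness, two_theta):
        t = attenuator_transmission(thickness, "Si", 8.48, two_theta)
        assert 0 < t <= 1
        assert attenuator_transmission(thickness * 1.1, "Si", 8.48, two_theta) < t
        if two_theta > 1e-3:  # below this, cos(2theta) == 1 to double precision
            assert attenuator_transmission(thickness, "Si", 8.48, 0.0) > t


class TestFluenceRatio:
    def test_reference_82_fold(self):
        assert fluence_ratio_to_saturation(7.8e12, 9.5e10) == pytest.approx(
            82, rel=0.01
        )

    def test_identity(self):
        assert fluence_ratio_to_saturation(5.0, 5.0) == 1.0

    def test_lf_ratio(self):
        assert fluence_ratio_to_saturation(1.3e11, 9.5e10) == pytest.approx(1.37, rel=0.01)


class TestProfileValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(DomainError):
            SpatialProfile(
                "double_gaussian",
                (GaussianComponent(0.5, 0.2), GaussianComponent(0.4, 0.6)),
            )

    def test_gate_must_fit_duration(self):
        with pytest.raises(DomainError):
            TemporalProfile(duration_fs=40.0, gate_fs=50.0)

    def test_quadrature_invariants(self):
        with pytest.raises(DomainError):
            FluenceQuadrature(np.array([1.0]), np.array([0.5]))
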