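import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phantomlight.optics_core import (
    DetectionAperture,
    OpticalSlab,
    aperture_angle,
    derive_coefficients,
    fresnel_reflectance,
)


class TestFresnelReflectance:
    def test_matched_indices_no_reflection(self):
        assert fresnel_reflectance(1.552, 1.552, 0.3) == pytest.approx(0.0, abs=1e-15)
        assert fresnel_reflectance(1.0, 1.0, 1.0) == pytest.approx(0.0, abs=1e-15)

    def test_normal_incidence_closed_form(self):
        # ((n1 - n2) / (n1 + n2))^2 for air -> glass-like resin
        expected = (0.552 / 2.552) ** 2
        assert fresnel_reflectance(1.0, 1.552, 1.0) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.04679, abs=5e-6)

    def test_total_internal_reflection(self):
        # critical angle arcsin(1/1.552) ~ 40.1 deg, so 80 deg is TIR
        assert fresnel_reflectance(1.552, 1.0, math.cos(math.radians(80))) == 1.0

    @pytest.mark.parametrize("bad_mu", [0.0, -0.5, 1.5])
    def test_invalid_mu_rejected(self, bad_mu):
        with pytest.raises(ValueError):
            fresnel_reflectance(1.0, 1.5, bad_mu)

    def test_invalid_index_rejected(self):
        with pytest.raises(ValueError):
            fresnel_reflectance(-1.0, 1.5, 0.5)

    @settings(max_examples=50, derandomize=True)
    @given(
        n1=st.floats(1.0, 2.5),
        n2=st.floats(1.0, 2.5),
    )
    def test_normal_incidence_reciprocity(self, n1, n2):
        assert fresnel_reflectance(n1, n2, 1.0) == pytest.approx(
            fresnel_reflectance(n2, n1, 1.0), abs=1e-14
        )

    @settings(max_examples=50, derandomize=True)
    @given(
        n1=st.floats(1.0, 2.0),
        n2=st.floats(1.0, 2.0),
        mu=st.floats(0.05, 0.999),
    )
    def test_continuity_away_from_critical_angle(self, n1, n2, mu):
        """Small change in mu gives a small change in R off the TIR kink."""
        sin_c2 = (n2 / n1) ** 2
        mu_c = math.sqrt(1 - sin_c2) if sin_c2 < 1 else 0.0
        if abs(mu - mu_c) < 0.02:
            return  # at the kink the derivative diverges
        h = 1e-6
        r0 = fresnel_reflectance(n1, n2, mu)
        r1 = fresnel_reflectance(n1, n2, min(mu + h, 1.0))
        assert abs(r1 - r0) < 1e-3

    def test_vectorized_matches_scalar(self):
        mus = np.array([0.2, 0.6, 1.0])
        vec = fresnel_reflectance(1.0, 1.552, mus)
        for m, v in zip(mus, vec):
            assert v == fresnel_reflectance(1.0, 1.552, float(m))


class TestApertureAngle:
    def test_full_hemisphere(self):
        assert aperture_angle(1.0, 1.0) == pytest.approx(math.pi / 2)

    @pytest.mark.parametrize(
        "na,expected", [(0.8, 0.9273), (0.4, 0.4115)]
    )
    def test_objective_apertures(self, na, expected):
        assert aperture_angle(na, 1.0) == pytest.approx(expected, abs=1e-4)

    def test_na_exceeding_index_rejected(self):
        with pytest.raises(ValueError):
            aperture_angle(1.2, 1.0)

    def test_nonpositive_na_rejected(self):
        with pytest.raises(ValueError):
            aperture_angle(0.0, 1.0)


class TestDeriveCoefficients:
    def test_isotropic_identity(self):
        # g = 0: mus equals mus' (phantom 1.2 values)
        der = derive_coefficients(3.781, 0.0, 0.0020, 0.947)
        assert der.mus == pytest.approx(3.781)

    @pytest.mark.parametrize("g", [0.0, 0.3, 0.6, 0.9])
    def test_tau_independent_of_g(self, g):
        der = derive_coefficients(3.688, g, 0.0034, 0.395)
        assert der.tau == pytest.approx(1.4568, abs=1e-4)

    @pytest.mark.parametrize("g", [0.0, 0.5, 0.9])
    def test_transport_mean_free_path(self, g):
        der = derive_coefficients(3.781, g, 0.0020, 0.947)
        assert der.l_transport == pytest.approx(0.26448, abs=1e-5)

    def test_nonscattering_has_infinite_transport_path(self):
        der = derive_coefficients(0.0, 0.0, 0.1, 1.0)
        assert math.isinf(der.l_transport)
        assert der.tau == 0.0

    def test_forward_limit_g1_rejected(self):
        with pytest.raises(ValueError):
            derive_coefficients(3.0, 1.0, 0.01, 1.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        mus_prime=st.floats(1e-3, 50.0),
        g=st.floats(0.0, 0.99),
        mua=st.floats(0.0, 1.0),
        d=st.floats(1e-3, 10.0),
    )
    def test_round_trip_recovers_mus_prime(self, mus_prime, g, mua, d):
        der = derive_coefficients(mus_prime, g, mua, d)
        assert der.mus * (1 - g) == pytest.approx(mus_prime, rel=1e-12)
        assert der.mut == pytest.approx(der.mus + mua, rel=1e-12)
        assert der.l_transport * mus_prime == pytest.approx(1.0, rel=1e-12)


class TestOpticalSlab:
    def test_derived_properties(self):
        slab = OpticalSlab(d=0.947, mus_prime=3.781, mua=0.0020, g=0.6)
        assert slab.mus == pytest.approx(3.781 / 0.4)
        assert slab.mut == pytest.approx(slab.mus + 0.0020)
        assert slab.tau == pytest.approx(3.781 * 0.947)
        assert slab.mus * (1 - slab.g) == pytest.approx(slab.mus_prime, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(d=-1.0, mus_prime=1.0, mua=0.0),
            dict(d=1.0, mus_prime=-1.0, mua=0.0),
            dict(d=1.0, mus_prime=1.0, mua=-0.1),
            dict(d=1.0, mus_prime=1.0, mua=0.0, g=1.0),
            dict(d=1.0, mus_prime=1.0, mua=0.0, n_slab=0.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OpticalSlab(**kwargs)


class TestDetectionAperture:
    def test_theta_max_and_interior_cutoff(self):
        ap = DetectionAperture(na=0.8)
        assert ap.theta_max == pytest.approx(math.asin(0.8))
        # NA is conserved across the interface: interior cutoff from na/n
        assert ap.mu_min_interior(1.552) == pytest.approx(
            math.sqrt(1 - (0.8 / 1.552) ** 2)
        )

    def test_na_larger_than_ambient_rejected(self):
        with pytest.raises(ValueError):
            DetectionAperture(na=1.1, n_ambient=1.0)
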