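import math

import numpy as np
import pytest

from phantomlight import (
    DetectionAperture,
    OpticalSlab,
    angular_transmittance,
    ballistic_transmittance,
    boundary_radiance,
    partial_transmittance,
    simulate,
    solve_pn,
)
from phantomlight.optics_core import fresnel_reflectance
from phantomlight.pn_solver import default_order, series_radiance

SAMPLE_12 = OpticalSlab(d=0.947, mus_prime=3.781, mua=0.0020, g=0.6, sample_id="1.2")
SAMPLE_13 = OpticalSlab(d=1.514, mus_prime=3.841, mua=0.0020, g=0.6, sample_id="1.3")


class TestSolvePN:
    def test_even_order_rejected(self):
        with pytest.raises(ValueError):
            solve_pn(SAMPLE_12, order=16)

    def test_nonscattering_slab_has_zero_diffuse_field(self):
        slab = OpticalSlab(d=1.0, mus_prime=0.0, mua=0.1, g=0.0)
        sol = solve_pn(slab, order=15)
        z = np.linspace(0, 1, 7)
        for l in range(4):
            assert np.all(sol.psi(z, l) == 0.0)
        mu = np.linspace(0.05, 1.0, 11)
        assert np.all(boundary_radiance(sol, "bottom", mu) == 0.0)

    def test_eigenvalue_spectrum_is_symmetric(self):
        sol = solve_pn(SAMPLE_12, order=15)
        # homogeneous rates (excluding the two collimated-driven terms)
        rates = np.sort(sol.alpha[:16])
        assert np.allclose(rates, -rates[::-1], rtol=1e-9)

    def test_diffuse_fluence_nonnegative(self):
        for slab in (SAMPLE_12, SAMPLE_13):
            sol = solve_pn(slab)
            z = np.linspace(0, slab.d, 101)
            psi0 = sol.psi(z, 0)
            assert np.all(psi0 >= -1e-10 * psi0.max())

    def test_default_order_resolves_phase_function(self):
        assert default_order(0.0) == 31
        assert default_order(0.9) % 2 == 1
        assert 0.9 ** default_order(0.9) < 1e-3

    def test_fluence_matches_monte_carlo_at_interior_depths(self):
        """P_N fluence (diffuse + collimated) vs MC collision estimator."""
        slab = SAMPLE_12
        sol = solve_pn(slab)
        res = simulate(slab, 200_000, seed=11, n_z_bins=10)
        zc = 0.5 * (res.z_edges[:-1] + res.z_edges[1:])
        col = sol.collimated
        mut = sol.mut_eff
        collimated = col.a * np.exp(-mut * zc) + col.b * np.exp(mut * (zc - slab.d))
        pn_total = sol.psi(zc, 0) + collimated
        for i in range(2, 7):  # five interior depths
            assert abs(res.fluence[i] - pn_total[i]) < 3 * res.se_fluence[i]


class TestBoundaryRadiance:
    def test_exact_fresnel_boundary_condition(self):
        """|L_in(mu) - R_F(mu) L_out(mu)| < 1e-10 max L at both faces."""
        sol = solve_pn(SAMPLE_13)
        mu = np.linspace(0.05, 1.0, 40)
        r = fresnel_reflectance(1.552, 1.0, mu)
        for face in ("top", "bottom"):
            l_out = boundary_radiance(sol, face, mu)
            l_in = boundary_radiance(sol, face, -mu)
            assert np.max(np.abs(l_in - r * l_out)) < 1e-10 * np.max(l_out)

    def test_grazing_direction_is_finite(self):
        sol = solve_pn(SAMPLE_12)
        val = boundary_radiance(sol, "bottom", 1e-9)
        assert np.isfinite(val) and val >= 0

    def test_invalid_direction_rejected(self):
        sol = solve_pn(SAMPLE_12)
        with pytest.raises(ValueError):
            boundary_radiance(sol, "bottom", 0.0)
        with pytest.raises(ValueError):
            boundary_radiance(sol, "middle", 0.5)

    def test_hybrid_form_smoother_than_series(self):
        """Regression guard: the naive Legendre series rings, the hybrid
        characteristic evaluation does not."""
        slab = OpticalSlab(d=0.395, mus_prime=3.688, mua=0.0034, g=0.6)
        sol = solve_pn(slab)
        mu = np.linspace(0.02, 1.0, 200)
        hybrid = boundary_radiance(sol, "bottom", mu)
        naive = series_radiance(sol, "bottom", mu)

        def roughness(y):
            return np.sum(np.abs(np.diff(y, 2))) / np.max(np.abs(y))

        assert roughness(naive) > 3.0 * roughness(hybrid)

    def test_matches_monte_carlo_angular_histogram(self):
        """Exit angular distribution vs MC histogram (18 bins, 1e6 photons)."""
        slab = OpticalSlab(
            d=0.901, mus_prime=2.724, mua=0.0213, g=0.6, sample_id="2.1"
        )
        sol = solve_pn(slab)
        res = simulate(slab, 10**6, seed=21, n_angle_bins=18)
        n_i, n_a = slab.n_slab, slab.n_ambient
        x, w = np.polynomial.legendre.leggauss(32)
        for b in range(18):
            th0, th1 = res.theta_edges[b], res.theta_edges[b + 1]
            th = 0.5 * (x + 1) * (th1 - th0) + th0
            wq = 0.5 * w * (th1 - th0)
            sin_i = np.clip(n_a * np.sin(th) / n_i, 0, 1)
            mu_i = np.sqrt(1 - sin_i**2)
            rad = boundary_radiance(sol, "bottom", mu_i)
            tf = 1 - fresnel_reflectance(n_i, n_a, mu_i)
            t_dif = (n_a / n_i) ** 2 * tf * np.cos(th) * rad / (2 * np.pi)
            pn_bin = float(np.sum(wq * t_dif * 2 * np.pi * np.sin(th)))
            assert abs(res.t_angular[b] - pn_bin) < 3 * res.se_angular[b]


class TestAngularTransmittance:
    def test_absorbing_only_slab_is_beer_lambert(self):
        slab = OpticalSlab(
            d=2.0, mus_prime=0.0, mua=0.25, g=0.0, n_slab=1.0, n_ambient=1.0
        )
        table = angular_transmittance(slab, order=15)
        assert np.all(table.t_diffuse == 0.0)
        assert table.t_total == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_energy_closure_all_phantoms(self, table1):
        for slab in table1:
            t = angular_transmittance(slab)
            assert t.t_total + t.r_total + t.a_total == pytest.approx(
                1.0, abs=1e-3
            )

    def test_energy_closure_conservative_matched(self):
        """Closure tightens to 1e-6 for mua = 0 with matched indices as the
        truncation order grows."""
        slab = OpticalSlab(
            d=1.0, mus_prime=2.0, mua=0.0, g=0.6, n_slab=1.0, n_ambient=1.0
        )
        t = angular_transmittance(slab, order=501)
        assert t.t_total + t.r_total + t.a_total == pytest.approx(1.0, abs=1e-6)

    def test_angular_integral_consistent_with_totals(self):
        """Hemispheric integral of t_diffuse equals t_total - ballistic."""
        slab = SAMPLE_12
        sol = solve_pn(slab)
        table = angular_transmittance(slab)
        n_i, n_a = slab.n_slab, slab.n_ambient
        x, w = np.polynomial.legendre.leggauss(200)
        th = 0.5 * (x + 1) * (math.pi / 2)
        wq = 0.5 * w * (math.pi / 2)
        sin_i = np.clip(n_a * np.sin(th) / n_i, 0, 1)
        mu_i = np.sqrt(1 - sin_i**2)
        rad = boundary_radiance(sol, "bottom", mu_i)
        tf = 1 - fresnel_reflectance(n_i, n_a, mu_i)
        t_dif = (n_a / n_i) ** 2 * tf * np.cos(th) * rad / (2 * np.pi)
        integral = float(np.sum(wq * t_dif * 2 * math.pi * np.sin(th)))
        assert integral == pytest.approx(
            table.t_total - table.t_ballistic, rel=1e-6
        )

    def test_order_insensitivity_in_diffusion_regime(self):
        slab = OpticalSlab(d=5.0, mus_prime=2.0, mua=0.002, g=0.6)  # tau = 10
        t1 = angular_transmittance(slab, order=1)
        t31 = angular_transmittance(slab, order=31)
        assert t1.t_total == pytest.approx(t31.t_total, rel=0.05)

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            angular_transmittance(SAMPLE_12, n_angles=1)


class TestPartialTransmittance:
    def test_full_aperture_recovers_total(self):
        table = angular_transmittance(SAMPLE_12)
        pt = partial_transmittance(SAMPLE_12, DetectionAperture(na=1.0))
        assert pt.t_na == pytest.approx(table.t_total, rel=1e-9)

    def test_monotone_in_na(self):
        nas = [0.2, 0.4, 0.6, 0.8, 1.0]
        vals = [
            partial_transmittance(SAMPLE_12, DetectionAperture(na=na)).t_na
            for na in nas
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_strictly_decreasing_in_mua(self):
        vals = []
        for mua in (0.001, 0.01, 0.05, 0.1):
            slab = OpticalSlab(d=1.0, mus_prime=3.0, mua=mua, g=0.6)
            vals.append(
                partial_transmittance(slab, DetectionAperture(na=0.8)).t_na
            )
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_thin_slab_limit_is_fresnel_capped(self):
        """As d -> 0 the slab transmits the specular series < 1, not 1."""
        slab = OpticalSlab(d=1e-6, mus_prime=3.688, mua=0.0034, g=0.6)
        pt = partial_transmittance(slab, DetectionAperture(na=0.8))
        r = (0.552 / 2.552) ** 2
        fresnel_cap = (1 - r) ** 2 / (1 - r**2)
        assert pt.t_na == pytest.approx(fresnel_cap, abs=1e-4)
        assert pt.t_na < 1.0

    def test_rise_and_decay_over_thickness(self):
        """T_NA - T_NA,ball has a single interior maximum over d in
        (0, 2.5] mm for set-1-like parameters."""
        ds = np.arange(0.025, 2.501, 0.025)
        ap = DetectionAperture(na=0.8)
        vals = []
        for d in ds:
            slab = OpticalSlab(d=float(d), mus_prime=3.781, mua=0.0020, g=0.6)
            pt = partial_transmittance(slab, ap)
            vals.append(pt.t_na - pt.t_na_ballistic)
        vals = np.array(vals)
        imax = int(np.argmax(vals))
        assert 0 < imax < len(ds) - 1
        signs = np.sign(np.diff(vals))
        assert int(np.sum(np.abs(np.diff(signs)) > 0)) == 1


class TestBallisticTransmittance:
    def test_matched_indices_beer_lambert(self):
        slab = OpticalSlab(
            d=1.0, mus_prime=0.5, mua=0.5, g=0.0, n_slab=1.0, n_ambient=1.0
        )  # mut d = 1
        assert ballistic_transmittance(slab) == pytest.approx(
            math.exp(-1.0), rel=1e-12
        )

    def test_transparent_slab_fresnel_series(self):
        slab = OpticalSlab(d=1.0, mus_prime=0.0, mua=0.0, g=0.0)
        r = (0.552 / 2.552) ** 2
        expected = (1 - r) ** 2 / (1 - r**2)
        assert ballistic_transmittance(slab) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.91061, abs=2e-5)

    def test_single_pass_flag_drops_reflection_series(self):
        slab = OpticalSlab(d=0.5, mus_prime=1.0, mua=0.01, g=0.3)
        full = ballistic_transmittance(slab)
        single = ballistic_transmittance(slab, single_pass=True)
        assert single < full
        r = (0.552 / 2.552) ** 2
        assert (full - single) / full < r**2 / (1 - r**2) + 1e-12
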