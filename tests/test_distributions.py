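"""Mover-stayer frailty distributions: densities, masses, moments, sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special

from msfrailty import (
    CPPVFParams,
    FrailtySpec,
    MSGammaParams,
    MSInvGaussParams,
    cdf,
    laplace_transform,
    moments,
    pdf_continuous,
    pdf_limit_at_zero,
    point_mass,
    quadrature_rule,
    sample,
)


def cp_density_series(rho, nu, u):
    """Independent oracle: Poisson-mixture series for the m = 1 density.

    f(u) = sum_{n>=1} (rho nu)^n u^{n-1} e^{-rho - nu u} / ((n-1)! n!),
    truncated when a term falls below 1e-16 of the running sum.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    out = np.zeros_like(u)
    for j, uj in enumerate(u):
        total = 0.0
        log_u = math.log(uj)
        for n in range(1, 800):
            log_term = (
                n * math.log(rho * nu)
                + (n - 1) * log_u
                - rho
                - nu * uj
                - special.gammaln(n)
                - special.gammaln(n + 1)
            )
            term = math.exp(log_term)
            total += term
            if term < 1e-16 * total:
                break
        out[j] = total
    return out


class TestPointMass:
    def test_cp_pvf_fitted_value(self, cp_table):
        assert point_mass(cp_table) == pytest.approx(0.631, abs=5e-4)

    def test_plain_gamma_has_no_stayers(self):
        assert point_mass(FrailtySpec("gamma", MSGammaParams(0.0, 3.81))) == 0.0

    def test_exp_identity(self):
        spec = FrailtySpec("cp_pvf", CPPVFParams(rho=math.log(2.0), nu=1.0))
        assert point_mass(spec) == pytest.approx(0.5, rel=1e-12)

    def test_ms_families_return_pi(self):
        assert point_mass(FrailtySpec("ms_gamma", MSGammaParams(0.25, 1.0))) == 0.25
        assert point_mass(FrailtySpec("ms_invgauss", MSInvGaussParams(0.334, 0.33))) == 0.334


class TestDensity:
    def test_cp_closed_form_matches_bessel_value(self):
        spec = FrailtySpec("cp_pvf", CPPVFParams(1.0, 1.0))
        expected = math.exp(-2.0) * special.i1(2.0)
        assert pdf_continuous(spec, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_ms_gamma_theta_one_is_scaled_exponential(self):
        spec = FrailtySpec("ms_gamma", MSGammaParams(0.25, 1.0))
        assert pdf_continuous(spec, 1.0) == pytest.approx(0.75 * math.exp(-1.0), rel=1e-12)

    def test_cp_density_near_zero_approaches_limit(self, cp_table):
        assert pdf_continuous(cp_table, 1e-8) == pytest.approx(51.23, abs=5e-3)

    @pytest.mark.parametrize(
        "rho,nu",
        [(0.1, 0.1), (0.46, 176.43), (5.0, 2.0), (50.0, 200.0), (200.0, 0.5)],
    )
    def test_bessel_vs_series_oracle(self, rho, nu):
        spec = FrailtySpec("cp_pvf", CPPVFParams(rho, nu))
        u = np.geomspace(1e-6, 50.0, 60)
        closed = pdf_continuous(spec, u)
        series = cp_density_series(rho, nu, u)
        np.testing.assert_allclose(closed, series, rtol=1e-10)

    def test_rejects_nonpositive_u(self, cp_table):
        with pytest.raises(ValueError):
            pdf_continuous(cp_table, 0.0)
        with pytest.raises(ValueError):
            pdf_continuous(cp_table, -1.0)

    def test_normalization_over_families(self, family_grid):
        for spec in family_grid:
            cont, _ = integrate.quad(
                lambda x: float(pdf_continuous(spec, x)), 0.0, np.inf, limit=400
            )
            assert cont + point_mass(spec) == pytest.approx(1.0, abs=1e-6), spec

    def test_ms_gamma_diverges_at_zero_when_theta_large(self):
        spec = FrailtySpec("ms_gamma", MSGammaParams(0.1, 3.81))
        small = pdf_continuous(spec, np.array([1e-3, 1e-6, 1e-9]))
        assert np.all(np.diff(small) > 0) and small[-1] > 1e3


class TestLimitAtZero:
    def test_fitted_value(self):
        assert pdf_limit_at_zero(CPPVFParams(0.46, 176.43)) == pytest.approx(51.23, abs=5e-3)

    def test_unit_parameters(self):
        assert pdf_limit_at_zero(CPPVFParams(1.0, 1.0)) == pytest.approx(math.exp(-1.0))

    def test_agrees_with_density_at_tiny_u(self):
        params = CPPVFParams(2.0, 3.0)
        limit = pdf_limit_at_zero(params)
        assert limit == pytest.approx(6.0 * math.exp(-2.0), rel=1e-12)
        near = float(pdf_continuous(FrailtySpec("cp_pvf", params), 1e-8))
        assert near == pytest.approx(limit, rel=1e-4)

    def test_requires_m_equal_one(self):
        with pytest.raises(ValueError):
            pdf_limit_at_zero(CPPVFParams(1.0, 1.0, m=2.0))


class TestMoments:
    def test_unit_mean_gamma_variance_is_theta(self):
        mean, var = moments(FrailtySpec("gamma", MSGammaParams(0.0, 3.81)))
        assert mean == 1.0 and var == pytest.approx(3.81)

    def test_ms_invgauss_mean_is_one_minus_pi(self):
        mean, var = moments(FrailtySpec("ms_invgauss", MSInvGaussParams(0.334, 0.33)))
        assert mean == pytest.approx(0.666)
        assert var == pytest.approx(0.666 * (1.0 / 0.33 + 0.334))

    def test_cp_mean_is_rho_over_nu(self, cp_table):
        mean, var = moments(cp_table)
        assert mean == pytest.approx(0.0026, abs=5e-5)
        assert var == pytest.approx(2.0 * 0.46 / 176.43**2)

    def test_invgauss_gamma_moment_equivalence(self):
        """mu=1 inverse Gaussian with shape psi matches the mover-stayer gamma
        with theta = 1/psi in mean and variance."""
        for pi, psi in [(0.1, 0.5), (0.334, 0.33), (0.0, 2.0)]:
            ig = moments(FrailtySpec("ms_invgauss", MSInvGaussParams(pi, psi)))
            ga = moments(FrailtySpec("ms_gamma", MSGammaParams(pi, 1.0 / psi)))
            assert ig == pytest.approx(ga)

    def test_moments_match_numerical_integrals(self, family_grid):
        for spec in family_grid:
            mean, var = moments(spec)
            m1, _ = integrate.quad(
                lambda x: x * float(pdf_continuous(spec, x)), 0.0, np.inf, limit=400
            )
            m2, _ = integrate.quad(
                lambda x: x * x * float(pdf_continuous(spec, x)), 0.0, np.inf, limit=400
            )
            assert m1 == pytest.approx(mean, abs=1e-7)
            assert m2 - m1**2 == pytest.approx(var, abs=1e-6)


class TestLaplaceTransform:
    def test_normalization_at_zero(self, cp_table):
        assert laplace_transform(cp_table.params, 0.0) == 1.0

    def test_limit_is_point_mass(self):
        assert laplace_transform(CPPVFParams(0.46, 176.43), 1e12) == pytest.approx(
            math.exp(-0.46), rel=1e-6
        )

    def test_unit_parameter_value(self):
        assert laplace_transform(CPPVFParams(1.0, 1.0), 1.0) == pytest.approx(
            math.exp(-0.5), rel=1e-12
        )

    @pytest.mark.parametrize("s", [0.0, 0.5, 3.0, 20.0, 100.0])
    def test_matches_numerical_integral(self, s, family_grid):
        for spec in family_grid:
            integral, _ = integrate.quad(
                lambda x: math.exp(-s * x) * float(pdf_continuous(spec, x)),
                0.0,
                np.inf,
                limit=400,
            )
            assert laplace_transform(spec, s) == pytest.approx(
                point_mass(spec) + integral, abs=1e-6
            )

    def test_rejects_negative_s(self, cp_table):
        with pytest.raises(ValueError):
            laplace_transform(cp_table.params, -0.1)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        rho=st.floats(0.05, 20.0),
        nu=st.floats(0.05, 300.0),
        s1=st.floats(0.0, 50.0),
        s2=st.floats(0.0, 50.0),
    )
    def test_monotone_decreasing_and_bounded(self, rho, nu, s1, s2):
        params = CPPVFParams(rho, nu)
        lo, hi = sorted([s1, s2])
        v_lo, v_hi = laplace_transform(params, lo), laplace_transform(params, hi)
        pm = math.exp(-rho)
        assert pm - 1e-12 <= v_hi <= v_lo <= 1.0 + 1e-12


class TestSampling:
    def test_cp_zero_fraction_matches_point_mass(self, cp_table):
        n = 100_000
        draws = sample(cp_table, n, 1)
        pm = point_mass(cp_table)
        sd = math.sqrt(pm * (1 - pm) / n)
        assert abs(np.mean(draws == 0.0) - pm) < 3 * sd

    def test_degenerate_stayer_population(self):
        spec = FrailtySpec("ms_gamma", MSGammaParams(1.0 - 1e-12, 1.0))
        assert np.all(sample(spec, 2000, 1) == 0.0)

    def test_reproducible_given_seed(self, cp_table):
        assert np.array_equal(sample(cp_table, 50, 7), sample(cp_table, 50, 7))

    def test_sample_moments_match_theory(self, family_grid):
        n = 100_000
        for spec in family_grid:
            mean, var = moments(spec)
            draws = sample(spec, n, 123)
            se_mean = math.sqrt(var / n)
            assert abs(draws.mean() - mean) < 4 * se_mean, spec
            # variance of the sample variance ~ (m4 - var^2)/n; use a loose factor
            assert abs(draws.var() - var) < 6 * var / math.sqrt(n) + 4 * se_mean, spec

    def test_cp_mean_small_parameters(self):
        draws = sample(FrailtySpec("cp_pvf", CPPVFParams(2.0, 3.0)), 100_000, 11)
        mean, var = 2.0 / 3.0, 2.0 * 2.0 / 9.0
        assert abs(draws.mean() - mean) < 3 * math.sqrt(var / 100_000)


class TestCDF:
    def test_starts_at_point_mass(self, cp_table):
        assert cdf(cp_table, 0.0) == pytest.approx(point_mass(cp_table), rel=1e-10)

    def test_tends_to_one(self, family_grid):
        for spec in family_grid:
            assert cdf(spec, 1e4) == pytest.approx(1.0, abs=1e-9)

    def test_ms_gamma_closed_form(self):
        spec = FrailtySpec("ms_gamma", MSGammaParams(0.2, 1.0))
        assert cdf(spec, 1.0) == pytest.approx(0.2 + 0.8 * (1 - math.exp(-1.0)), rel=1e-10)

    def test_monotone(self, family_grid):
        u = np.linspace(0.0, 20.0, 200)
        for spec in family_grid:
            vals = cdf(spec, u)
            assert np.all(np.diff(vals) >= -1e-12)

    def test_matches_density_integral(self, cp_table):
        upto, _ = integrate.quad(lambda x: float(pdf_continuous(cp_table, x)), 0, 0.01)
        assert cdf(cp_table, 0.01) == pytest.approx(point_mass(cp_table) + upto, abs=1e-9)


class TestQuadrature:
    def test_normalization_and_mean(self, family_grid):
        for spec in family_grid:
            nodes, weights = quadrature_rule(spec, 40)
            assert np.all(nodes > 0.0)
            pm = point_mass(spec)
            assert weights.sum() == pytest.approx(1.0 - pm, abs=1e-6), spec
            mover_mean = moments(spec)[0]  # stayers contribute 0 to the mean
            assert weights @ nodes == pytest.approx(mover_mean, abs=1e-4), spec

    def test_laplace_integrand(self):
        spec = FrailtySpec("cp_pvf", CPPVFParams(1.0, 1.0))
        nodes, weights = quadrature_rule(spec, 40)
        expected = math.exp(-0.5) - math.exp(-1.0)  # transform minus point mass
        assert weights @ np.exp(-nodes) == pytest.approx(expected, abs=1e-6)

    def test_warns_when_too_few_nodes(self):
        spec = FrailtySpec("ms_invgauss", MSInvGaussParams(0.3, 0.05))
        with pytest.warns(RuntimeWarning):
            quadrature_rule(spec, 2)

    def test_rejects_tiny_rule(self, cp_table):
        with pytest.raises(ValueError):
            quadrature_rule(cp_table, 1)


class TestSpecValidation:
    def test_family_param_mismatch(self):
        with pytest.raises(ValueError):
            FrailtySpec("cp_pvf", MSGammaParams(0.1, 1.0))

    def test_plain_gamma_requires_zero_pi(self):
        with pytest.raises(ValueError):
            FrailtySpec("gamma", MSGammaParams(0.2, 1.0))

    @pytest.mark.parametrize("pi", [-0.1, 1.0, 1.5])
    def test_pi_range(self, pi):
        with pytest.raises(ValueError):
            MSGammaParams(pi, 1.0)

    def test_roundtrip_dict(self, cp_table):
        assert FrailtySpec.from_dict(cp_table.to_dict()) == cp_table
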