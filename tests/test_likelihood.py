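"""Marginal likelihood, constraints, parameter packing, stayer regression."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from msfrailty import (
    BaselineIntensities,
    CovariateEffects,
    CPPVFParams,
    FrailtySpec,
    MSGammaParams,
    MSInvGaussParams,
    ModelSpec,
    moments,
    ParameterVector,
    PatientPanel,
    StayerRegression,
    apply_constraints,
    patient_conditional_lik,
    patient_marginal_loglik,
    pdf_continuous,
    point_mass,
    scenario_from_table1,
    simulate_cohort,
    stayer_probability,
    total_loglik,
)
from msfrailty.likelihood import CohortLikelihood, ModelParams

from conftest import make_visits

BASELINES = BaselineIntensities(0.28e-2, 0.27e-2, 2.15e-2, 2.34e-2)


def small_cohort(n=30, family="ms_gamma", seed=2):
    sc = scenario_from_table1(family, n_patients=n, seed=seed, n_locations=4)
    return simulate_cohort(sc), sc


class TestStayerProbability:
    def test_constant_when_slope_zero(self):
        reg = StayerRegression((-0.5, 0.0))
        x = np.linspace(-3, 3, 7)[:, None]
        pi = stayer_probability(reg, x)
        assert np.allclose(pi, pi[0])

    def test_cloglog_at_fitted_intercept(self):
        # delta_0 = -1.27 with x = 0 under the complementary log-log link
        reg = StayerRegression((-1.27, -1.03))
        pi0 = float(stayer_probability(reg, [[0.0]])[0])
        assert pi0 == pytest.approx(1.0 - math.exp(-math.exp(-1.27)), rel=1e-12)
        assert pi0 == pytest.approx(0.245, abs=5e-3)

    def test_negative_slope_means_decreasing_pi(self):
        reg = StayerRegression((-1.27, -1.03))
        x = np.linspace(-2, 2, 9)[:, None]
        pi = stayer_probability(reg, x)
        assert np.all(np.diff(pi) < 0)

    def test_cloglog_increasing_in_linear_predictor(self):
        reg = StayerRegression((0.0, 1.0), link="cloglog_on_pi")
        x = np.linspace(-4, 4, 11)[:, None]
        assert np.all(np.diff(stayer_probability(reg, x)) > 0)

    def test_loglog_link_maps_to_cp_rate(self):
        # log(-log pi) = eta  <=>  rho = exp(eta), pi = exp(-rho)
        reg = StayerRegression((0.3, 0.7), link="loglog_on_pi")
        eta = 0.3 + 0.7 * 1.5
        assert float(stayer_probability(reg, [[1.5]])[0]) == pytest.approx(
            math.exp(-math.exp(eta)), rel=1e-12
        )


class TestParameterVector:
    @pytest.mark.parametrize(
        "spec",
        [
            ModelSpec("gamma"),
            ModelSpec("ms_gamma"),
            ModelSpec("ms_invgauss"),
            ModelSpec("cp_pvf"),
            ModelSpec("ms_invgauss", fix_pstayer_zero=True),
            ModelSpec("ms_invgauss", stayer_covariate_names=("esr",)),
            ModelSpec("cp_pvf", stayer_covariate_names=("esr",)),
            ModelSpec("ms_gamma", with_activity_covariates=False),
        ],
    )
    def test_pack_unpack_roundtrip(self, spec):
        pvec = ParameterVector(spec)
        rng = np.random.default_rng(4)
        x = rng.normal(scale=0.8, size=pvec.size)
        params = pvec.unpack(x)
        np.testing.assert_allclose(pvec.pack(params), x, atol=1e-12)

    def test_anchor_scheme_fixes_lambda12(self):
        pvec = ParameterVector(ModelSpec("cp_pvf"))
        params = pvec.unpack(np.zeros(pvec.size))
        assert params.baselines.lambda_12 == 1.0
        assert "log_lambda_12" not in pvec.names

    def test_pstayer_coordinate_mapping(self):
        pv_pi = ParameterVector(ModelSpec("ms_invgauss"))
        assert pv_pi.pstayer_name == "logit_pi"
        assert pv_pi.pstayer_coordinate(0.5) == pytest.approx(0.0)
        pv_rho = ParameterVector(ModelSpec("cp_pvf"))
        assert pv_rho.pstayer_name == "log_rho"
        assert pv_rho.pstayer_coordinate(math.exp(-1.0)) == pytest.approx(0.0)

    def test_scheme_family_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("ms_gamma", constraint_scheme="anchor_lambda12")
        with pytest.raises(ValueError):
            ModelSpec("cp_pvf", constraint_scheme="unit_mover_mean")
        with pytest.raises(ValueError):
            ModelSpec("ms_gamma", stayer_covariate_names=("esr",))


class TestApplyConstraints:
    def test_cp_reported_baseline_is_rho_over_nu(self):
        spec = ModelSpec("cp_pvf")
        params = ModelParams(
            baselines=BaselineIntensities(1.0, 0.96, 7.5, 7.46),
            effects=CovariateEffects(),
            frailty=FrailtySpec("cp_pvf", CPPVFParams(0.46, 176.43)),
        )
        rep = apply_constraints(spec, params)
        assert rep["baselines_reported"]["lambda_12"] * 100 == pytest.approx(0.26, abs=5e-3)
        assert rep["baselines_reported"]["lambda_13"] == pytest.approx(
            (0.46 / 176.43) * 0.96, rel=1e-12
        )

    def test_unit_mover_mean_gamma(self):
        spec = ModelSpec("ms_gamma")
        params = ModelParams(
            baselines=BASELINES,
            effects=CovariateEffects(),
            frailty=FrailtySpec("ms_gamma", MSGammaParams(0.1, 2.0)),
        )
        rep = apply_constraints(spec, params)
        assert rep["mover_gamma_shape"] == rep["mover_gamma_rate"] == 0.5
        assert rep["baselines_reported"]["lambda_12"] == BASELINES.lambda_12


class TestMarginalLikelihood:
    def test_quiet_panel_with_near_total_stayer_mass(self, quiet_panel):
        spec = ModelSpec("ms_gamma", with_activity_covariates=False)
        params = ModelParams(
            baselines=BASELINES,
            effects=CovariateEffects(),
            frailty=FrailtySpec("ms_gamma", MSGammaParams(1.0 - 1e-9, 1.0)),
        )
        ll = patient_marginal_loglik(quiet_panel, spec, params)
        assert ll == pytest.approx(0.0, abs=1e-6)

    def test_damaged_panel_impossible_for_pure_stayers(self, damaged_panel):
        spec = ModelSpec("ms_gamma", with_activity_covariates=False)
        params = ModelParams(
            baselines=BASELINES,
            effects=CovariateEffects(),
            frailty=FrailtySpec("ms_gamma", MSGammaParams(1.0 - 1e-15, 1e-6)),
        )
        ll = patient_marginal_loglik(damaged_panel, spec, params)
        assert ll < -10.0  # essentially impossible

    def test_degenerate_gamma_frailty_recovers_conditional(self, damaged_panel):
        # theta -> 0 concentrates the frailty at u = 1
        spec = ModelSpec("gamma", with_activity_covariates=False)
        params = ModelParams(
            baselines=BASELINES,
            effects=CovariateEffects(),
            frailty=FrailtySpec("gamma", MSGammaParams(0.0, 1e-8)),
        )
        marg = patient_marginal_loglik(damaged_panel, spec, params)
        cond = math.log(
            patient_conditional_lik(damaged_panel, BASELINES, CovariateEffects(), 1.0)
        )
        assert marg == pytest.approx(cond, abs=1e-4)

    def test_additivity_on_duplicated_cohort(self):
        panels, sc = small_cohort(10)
        spec = ModelSpec("ms_gamma", n_quadrature_nodes=24)
        params = ModelParams(baselines=sc.baselines, effects=sc.effects, frailty=sc.frailty)
        one = total_loglik(panels, spec, params)
        renamed = [
            PatientPanel(p.patient_id + "_b", p.locations, p.baseline_covariates)
            for p in panels
        ]
        two = total_loglik(panels + renamed, spec, params)
        assert two == pytest.approx(2 * one, rel=1e-12)

    @pytest.mark.parametrize("family", ["ms_gamma", "ms_invgauss", "cp_pvf"])
    def test_total_matches_adaptive_quadrature_oracle(self, family):
        """Fixed-rule frailty integral vs scipy adaptive quadrature per patient."""
        panels, sc = small_cohort(8, family=family, seed=5)
        spec = ModelSpec(family, n_quadrature_nodes=64)
        params = ModelParams(baselines=sc.baselines, effects=sc.effects, frailty=sc.frailty)
        fast = total_loglik(panels, spec, params)
        pm = point_mass(sc.frailty)
        oracle = 0.0
        for p in panels:

            def integrand(u):
                return patient_conditional_lik(
                    p, sc.baselines, sc.effects, u
                ) * float(pdf_continuous(sc.frailty, u))

            # split at the mover scale so adaptive quadrature resolves both the
            # (possibly singular) origin and the tail; tight relative tolerance
            # because patient likelihoods can be ~1e-12
            split = moments(sc.frailty)[0] / (1.0 - pm)
            a, _ = integrate.quad(integrand, 0.0, split, limit=400, epsabs=0, epsrel=1e-11)
            b, _ = integrate.quad(integrand, split, np.inf, limit=400, epsabs=0, epsrel=1e-11)
            oracle += math.log((pm if p.is_observed_stayer else 0.0) + a + b)
        assert fast == pytest.approx(oracle, abs=1e-4)

    def test_pi_zero_reproduces_plain_family(self):
        panels, sc = small_cohort(15, family="gamma", seed=8)
        effects, base = sc.effects, sc.baselines
        plain = ModelParams(
            baselines=base,
            effects=effects,
            frailty=FrailtySpec("gamma", MSGammaParams(0.0, 3.81)),
        )
        ms = ModelParams(
            baselines=base,
            effects=effects,
            frailty=FrailtySpec("ms_gamma", MSGammaParams(0.0, 3.81)),
        )
        ll_plain = total_loglik(panels, ModelSpec("gamma"), plain)
        ll_ms = total_loglik(panels, ModelSpec("ms_gamma"), ms)
        assert ll_ms == pytest.approx(ll_plain, rel=1e-12)

    def test_quadrature_refinement_diagnostic(self):
        panels, sc = small_cohort(20, family="cp_pvf", seed=3)
        params = ModelParams(baselines=sc.baselines, effects=sc.effects, frailty=sc.frailty)
        coarse = total_loglik(panels, ModelSpec("cp_pvf", n_quadrature_nodes=64), params)
        fine = total_loglik(panels, ModelSpec("cp_pvf", n_quadrature_nodes=128), params)
        assert abs(fine - coarse) < 1e-4

    def test_marginal_bounded_by_conditional_extremes(self, damaged_panel):
        spec = ModelSpec("ms_gamma", with_activity_covariates=False)
        frailty = FrailtySpec("ms_gamma", MSGammaParams(0.3, 1.0))
        params = ModelParams(
            baselines=BASELINES, effects=CovariateEffects(), frailty=frailty
        )
        marg = math.exp(patient_marginal_loglik(damaged_panel, spec, params))
        u_grid = np.geomspace(1e-4, 200, 400)
        conds = [
            patient_conditional_lik(damaged_panel, BASELINES, CovariateEffects(), u)
            for u in u_grid
        ]
        assert marg <= max(max(conds), 0.0) + 1e-12
        assert marg >= 0.0

    def test_stayer_regression_marginal_matches_manual(self):
        """Patient-specific pi_k via the cloglog link against a hand-built mixture."""
        reg = StayerRegression((-0.3, -0.8))
        spec = ModelSpec(
            "ms_invgauss", stayer_covariate_names=("esr",), n_quadrature_nodes=40
        )
        x_val = 0.7
        panel = PatientPanel(
            "p1",
            {1: make_visits([(0.0, 1), (1.0, 1), (2.3, 1)])},
            baseline_covariates={"esr": x_val},
        )
        params = ModelParams(
            baselines=BASELINES, effects=CovariateEffects(), stayer_reg=reg, shape=0.5
        )
        ll = patient_marginal_loglik(panel, spec, params)
        pi_k = float(stayer_probability(reg, [[x_val]])[0])
        mover = FrailtySpec("ms_invgauss", MSInvGaussParams(0.0, 0.5))
        integral, _ = integrate.quad(
            lambda u: patient_conditional_lik(panel, BASELINES, CovariateEffects(), u)
            * float(pdf_continuous(mover, u)),
            0,
            np.inf,
            limit=300,
        )
        expected = math.log(pi_k + (1.0 - pi_k) * integral)
        assert ll == pytest.approx(expected, abs=1e-6)

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(scale=st.floats(1.0, 5.0))
    def test_quiet_marginal_nonincreasing_in_baselines(self, scale):
        panel = PatientPanel(
            "quiet",
            {
                1: make_visits([(0.0, 1), (1.0, 1), (2.0, 1)]),
                2: make_visits([(0.0, 1), (1.1, 1)]),
            },
        )
        spec = ModelSpec("ms_gamma", with_activity_covariates=False)
        frailty = FrailtySpec("ms_gamma", MSGammaParams(0.2, 1.5))
        base_hi = BaselineIntensities(*(scale * b for b in BASELINES.as_array()))
        ll_lo = patient_marginal_loglik(
            panel, spec, ModelParams(BASELINES, CovariateEffects(), frailty=frailty)
        )
        ll_hi = patient_marginal_loglik(
            panel, spec, ModelParams(base_hi, CovariateEffects(), frailty=frailty)
        )
        assert ll_hi <= ll_lo + 1e-12
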