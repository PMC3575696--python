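"""Marginal likelihood over the mover-stayer frailty.

A patient contributes

    L_k = pi_k * S_k + integral_0^inf  L_k(u) f_cont(u) du

where S_k is 1 when every observed state at every location is the
undamaged state (the patient is *consistent* with being a stayer),
L_k(u) is the conditional panel likelihood given frailty u, and f_cont
the continuous part of the frailty density.  The integral is evaluated
with the family-specific quadrature rule of :mod:`msfrailty.distributions`.

Identifiability constraints
---------------------------
``unit_mover_mean`` (gamma / inverse Gaussian families): the mover
component has mean exactly 1, so baseline intensities are on the
natural per-year scale.  ``anchor_lambda12`` (compound Poisson): the
frailty mean rho/nu is free, lambda0_12 is fixed at 1 and the other
baselines are relative to it; reported baselines are (rho/nu) times the
relative rates.

The stayer probability may depend on patient-level covariates through a
link g: either the complementary log-log of pi,
log(-log(1 - pi_k)) = delta' x_k, or the log-log form
log(-log pi_k) = delta' x_k, which for the compound Poisson family is
equivalent to rho_k = exp(delta' x_k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math

import numpy as np
from scipy.special import expit

from . import distributions as dist
from .distributions import CPPVFParams, FrailtySpec, MSGammaParams, MSInvGaussParams
from .multistate import (
    BaselineIntensities,
    CovariateEffects,
    IntervalData,
    PatientPanel,
    conditional_loglik_by_patient,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "StayerRegression",
    "ParameterVector",
    "ModelParams",
    "stayer_probability",
    "patient_marginal_loglik",
    "total_loglik",
    "apply_constraints",
    "CohortLikelihood",
]

CONSTRAINT_SCHEMES = ("unit_mover_mean", "anchor_lambda12")
STAYER_LINKS = ("cloglog_on_pi", "loglog_on_pi")


@dataclass(frozen=True)
class ModelSpec:
    """Which frailty family, constraint scheme and stayer link a model uses."""

    frailty_family: str
    constraint_scheme: str = ""
    stayer_link: str = "cloglog_on_pi"
    stayer_covariate_names: tuple = ()
    with_activity_covariates: bool = True
    n_quadrature_nodes: int = 64
    fix_pstayer_zero: bool = False

    def __post_init__(self) -> None:
        if self.frailty_family not in dist.FAMILIES:
            raise ValueError(f"unknown frailty family {self.frailty_family!r}")
        if self.fix_pstayer_zero and self.frailty_family not in ("ms_gamma", "ms_invgauss"):
            raise ValueError(
                "fix_pstayer_zero defines the pi = 0 submodel of the ms_gamma / "
                "ms_invgauss families only"
            )
        if self.fix_pstayer_zero and self.has_stayer_regression:
            raise ValueError("cannot fix pi = 0 in a stayer-regression model")
        scheme = self.constraint_scheme
        if not scheme:
            scheme = "anchor_lambda12" if self.frailty_family == "cp_pvf" else "unit_mover_mean"
            object.__setattr__(self, "constraint_scheme", scheme)
        if scheme not in CONSTRAINT_SCHEMES:
            raise ValueError(f"unknown constraint scheme {scheme!r}")
        if scheme == "anchor_lambda12" and self.frailty_family != "cp_pvf":
            raise ValueError("anchor_lambda12 is only meaningful for the cp_pvf family")
        if scheme == "unit_mover_mean" and self.frailty_family == "cp_pvf":
            raise ValueError("cp_pvf uses the anchor_lambda12 scheme (rho/nu is its mean)")
        if self.stayer_link not in STAYER_LINKS:
            raise ValueError(f"unknown stayer link {self.stayer_link!r}")
        if self.stayer_covariate_names and self.frailty_family not in ("ms_invgauss", "cp_pvf"):
            raise ValueError(
                "covariate-dependent stayer probabilities are supported for the "
                "ms_invgauss and cp_pvf families only"
            )
        object.__setattr__(self, "stayer_covariate_names", tuple(self.stayer_covariate_names))

    @property
    def has_stayer_regression(self) -> bool:
        return len(self.stayer_covariate_names) > 0

    def to_dict(self) -> dict:
        return {
            "frailty_family": self.frailty_family,
            "constraint_scheme": self.constraint_scheme,
            "stayer_link": self.stayer_link,
            "stayer_covariate_names": list(self.stayer_covariate_names),
            "with_activity_covariates": self.with_activity_covariates,
            "n_quadrature_nodes": self.n_quadrature_nodes,
            "fix_pstayer_zero": self.fix_pstayer_zero,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["stayer_covariate_names"] = tuple(d.get("stayer_covariate_names", ()))
        return cls(**d)


@dataclass(frozen=True)
class StayerRegression:
    """Link-scale coefficients (delta_0, delta_1, ...) for P(Stayer | x)."""

    deltas: tuple
    link: str = "cloglog_on_pi"

    def __post_init__(self) -> None:
        object.__setattr__(self, "deltas", tuple(float(d) for d in self.deltas))
        if not all(math.isfinite(d) for d in self.deltas):
            raise ValueError("stayer regression coefficients must be finite")
        if self.link not in STAYER_LINKS:
            raise ValueError(f"unknown stayer link {self.link!r}")

    def linear_predictor(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        d = np.asarray(self.deltas)
        if x.shape[1] != d.size - 1:
            raise ValueError(f"expected {d.size - 1} covariates, got {x.shape[1]}")
        return d[0] + x @ d[1:]


def stayer_probability(reg: StayerRegression, x, link: str | None = None) -> np.ndarray:
    """P(Stayer) for covariate values x under the regression's link.

    cloglog_on_pi:  pi = 1 - exp(-exp(eta)),  increasing in eta;
    loglog_on_pi:   pi = exp(-exp(eta))  (equivalently rho = exp(eta)
    for the compound Poisson family), decreasing in eta.
    """
    link = link or reg.link
    eta = reg.linear_predictor(x)
    if link == "cloglog_on_pi":
        pi = -np.expm1(-np.exp(eta))
    elif link == "loglog_on_pi":
        pi = np.exp(-np.exp(eta))
    else:
        raise ValueError(f"unknown stayer link {link!r}")
    return pi


@dataclass
class ModelParams:
    """Natural-scale parameters of one model.

    Exactly one of ``frailty`` (shared frailty distribution) or
    ``stayer_reg`` + ``shape`` (covariate-dependent stayer probability
    with a shared mover shape parameter: psi for ms_invgauss, nu for
    cp_pvf) is set.
    """

    baselines: BaselineIntensities
    effects: CovariateEffects
    frailty: FrailtySpec | None = None
    stayer_reg: StayerRegression | None = None
    shape: float | None = None

    def frailty_for_pi(self, family: str, pi_k: float) -> FrailtySpec:
        """Patient-specific frailty spec given that patient's stayer probability."""
        if family == "ms_invgauss":
            return FrailtySpec(family, MSInvGaussParams(pi=pi_k, psi=self.shape, mu=1.0))
        if family == "cp_pvf":
            return FrailtySpec(family, CPPVFParams(rho=-math.log(pi_k), nu=self.shape))
        raise ValueError(f"stayer regression unsupported for family {family!r}")


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


class ParameterVector:
    """Bijective packing of ModelParams into an unconstrained real vector.

    Baselines and positive frailty parameters travel on the log scale,
    the stayer probability pi on the logit scale, covariate effects and
    stayer-regression deltas on the natural scale.  Under the
    anchor_lambda12 scheme lambda0_12 is fixed at 1 and carries no
    coordinate.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        names: list[str] = []
        if spec.constraint_scheme == "anchor_lambda12":
            names += ["log_lambda_13", "log_lambda_24", "log_lambda_34"]
        else:
            names += ["log_lambda_12", "log_lambda_13", "log_lambda_24", "log_lambda_34"]
        if spec.with_activity_covariates:
            names += [
                "beta_nd_tender",
                "beta_nd_effusion",
                "beta_nd_opp_active",
                "beta_nd_past",
                "beta_nd_opp_past",
                "beta_od_tender",
                "beta_od_effusion",
                "beta_od_past",
            ]
        fam = spec.frailty_family
        if spec.has_stayer_regression:
            names += [f"delta_{i}" for i in range(len(spec.stayer_covariate_names) + 1)]
            names += ["log_psi" if fam == "ms_invgauss" else "log_nu"]
        else:
            pi_coord = [] if spec.fix_pstayer_zero else ["logit_pi"]
            if fam == "gamma":
                names += ["log_theta"]
            elif fam == "ms_gamma":
                names += pi_coord + ["log_theta"]
            elif fam == "ms_invgauss":
                names += pi_coord + ["log_psi"]
            else:  # cp_pvf
                names += ["log_rho", "log_nu"]
        self.names = names

    @property
    def size(self) -> int:
        return len(self.names)

    @property
    def pstayer_name(self) -> str | None:
        """Name of the coordinate governing P(Stayer), if the model has one."""
        for candidate in ("logit_pi", "log_rho"):
            if candidate in self.names:
                return candidate
        return None

    @property
    def pstayer_index(self) -> int | None:
        name = self.pstayer_name
        return self.names.index(name) if name is not None else None

    def pstayer_coordinate(self, p_stayer: float) -> float:
        """Unconstrained coordinate value corresponding to P(Stayer) = p_stayer."""
        if self.pstayer_name == "logit_pi":
            return _logit(p_stayer)
        if self.pstayer_name == "log_rho":
            return math.log(-math.log(p_stayer))
        raise ValueError("model has no single P(Stayer) coordinate")

    def pack(self, params: ModelParams) -> np.ndarray:
        spec = self.spec
        x: list[float] = []
        b = params.baselines
        if spec.constraint_scheme == "anchor_lambda12":
            if abs(b.lambda_12 - 1.0) > 1e-12:
                raise ValueError("anchor_lambda12 requires lambda_12 = 1 on the working scale")
            x += [math.log(b.lambda_13), math.log(b.lambda_24), math.log(b.lambda_34)]
        else:
            x += [
                math.log(b.lambda_12),
                math.log(b.lambda_13),
                math.log(b.lambda_24),
                math.log(b.lambda_34),
            ]
        if spec.with_activity_covariates:
            x += list(params.effects.beta_nodamage) + list(params.effects.beta_oppdamaged)
        fam = spec.frailty_family
        if spec.has_stayer_regression:
            if params.stayer_reg is None or params.shape is None:
                raise ValueError("stayer regression model needs stayer_reg and shape")
            x += list(params.stayer_reg.deltas)
            x += [math.log(params.shape)]
        else:
            p = params.frailty.params
            fixed_pi = spec.fix_pstayer_zero
            if fixed_pi and p.pi != 0.0:
                raise ValueError("fix_pstayer_zero model requires frailty with pi = 0")
            if fam == "gamma":
                x += [math.log(p.theta)]
            elif fam == "ms_gamma":
                x += ([] if fixed_pi else [_logit(p.pi)]) + [math.log(p.theta)]
            elif fam == "ms_invgauss":
                x += ([] if fixed_pi else [_logit(p.pi)]) + [math.log(p.psi)]
            else:
                x += [math.log(p.rho), math.log(p.nu)]
        return np.asarray(x, dtype=float)

    def unpack(self, x: np.ndarray) -> ModelParams:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.size,):
            raise ValueError(f"expected vector of length {self.size}, got {x.shape}")
        spec = self.spec
        i = 0
        if spec.constraint_scheme == "anchor_lambda12":
            lam = [1.0, *np.exp(x[i : i + 3])]
            i += 3
        else:
            lam = list(np.exp(x[i : i + 4]))
            i += 4
        baselines = BaselineIntensities(*lam)
        if spec.with_activity_covariates:
            effects = CovariateEffects(tuple(x[i : i + 5]), tuple(x[i + 5 : i + 8]))
            i += 8
        else:
            effects = CovariateEffects()
        fam = spec.frailty_family
        if spec.has_stayer_regression:
            n_delta = len(spec.stayer_covariate_names) + 1
            reg = StayerRegression(tuple(x[i : i + n_delta]), link=spec.stayer_link)
            shape = math.exp(x[i + n_delta])
            return ModelParams(baselines, effects, stayer_reg=reg, shape=shape)
        fixed_pi = spec.fix_pstayer_zero
        if fam == "gamma":
            frailty = FrailtySpec("gamma", MSGammaParams(pi=0.0, theta=math.exp(x[i])))
        elif fam == "ms_gamma":
            pi = 0.0 if fixed_pi else float(expit(x[i]))
            frailty = FrailtySpec(
                "ms_gamma", MSGammaParams(pi=pi, theta=math.exp(x[i + (0 if fixed_pi else 1)]))
            )
        elif fam == "ms_invgauss":
            pi = 0.0 if fixed_pi else float(expit(x[i]))
            frailty = FrailtySpec(
                "ms_invgauss",
                MSInvGaussParams(pi=pi, psi=math.exp(x[i + (0 if fixed_pi else 1)]), mu=1.0),
            )
        else:
            frailty = FrailtySpec(
                "cp_pvf", CPPVFParams(rho=math.exp(x[i]), nu=math.exp(x[i + 1]))
            )
        return ModelParams(baselines, effects, frailty=frailty)


def apply_constraints(spec: ModelSpec, params: ModelParams) -> dict:
    """Natural-scale reporting values under the model's identifiability scheme.

    For anchor_lambda12 the reported baseline i->j intensity is
    (rho/nu) * lambda_ij(relative), i.e. the expected intensity at
    covariate zero, with lambda_12 itself reported as rho/nu.
    """
    out: dict = {"constraint_scheme": spec.constraint_scheme}
    b = params.baselines
    if spec.constraint_scheme == "anchor_lambda12":
        if params.frailty is not None:
            p = params.frailty.params
            mean_u = p.rho * p.m / p.nu
        else:
            mean_u = None  # per-patient rho; no single frailty mean
        out["baselines_relative"] = {
            "lambda_12": b.lambda_12,
            "lambda_13": b.lambda_13,
            "lambda_24": b.lambda_24,
            "lambda_34": b.lambda_34,
        }
        if mean_u is not None:
            out["baselines_reported"] = {
                "lambda_12": mean_u * b.lambda_12,
                "lambda_13": mean_u * b.lambda_13,
                "lambda_24": mean_u * b.lambda_24,
                "lambda_34": mean_u * b.lambda_34,
            }
            out["frailty_mean"] = mean_u
    else:
        out["baselines_reported"] = {
            "lambda_12": b.lambda_12,
            "lambda_13": b.lambda_13,
            "lambda_24": b.lambda_24,
            "lambda_34": b.lambda_34,
        }
        if params.frailty is not None and spec.frailty_family in ("gamma", "ms_gamma"):
            # unit mover mean: Gamma(1/theta, rate 1/theta)
            theta = params.frailty.params.theta
            out["mover_gamma_shape"] = out["mover_gamma_rate"] = 1.0 / theta
        if params.frailty is not None and spec.frailty_family == "ms_invgauss":
            if params.frailty.params.mu != 1.0:
                raise ValueError("unit_mover_mean requires mu = 1 for the inverse Gaussian")
    if spec.with_activity_covariates:
        nd, od = params.effects.as_arrays()
        out["intensity_ratios"] = {
            "nd_tender": float(np.exp(nd[0])),
            "nd_effusion": float(np.exp(nd[1])),
            "nd_opp_active": float(np.exp(nd[2])),
            "nd_past": float(np.exp(nd[3])),
            "nd_opp_past": float(np.exp(nd[4])),
            "od_tender": float(np.exp(od[0])),
            "od_effusion": float(np.exp(od[1])),
            "od_past": float(np.exp(od[2])),
        }
    return out


class CohortLikelihood:
    """Preprocessed cohort with a fast marginal log-likelihood.

    Flattens all observation intervals into arrays once, records the
    stayer indicator S_k per patient, and evaluates the frailty
    integral with a fixed-size quadrature rule at each parameter value.
    """

    def __init__(self, panels, spec: ModelSpec):
        panels = list(panels)
        if not panels:
            raise ValueError("empty cohort")
        self.spec = spec
        self.panels = panels
        self.pvec = ParameterVector(spec)
        singles = sum(1 for p in panels if p.n_informative_locations == 0)
        if singles:
            logger.warning(
                "%d patient(s) have no location with >= 2 visits and contribute factor 1",
                singles,
            )
        self._informative = [p for p in panels if p.n_informative_locations > 0]
        self.data = IntervalData.from_panels(self._informative)
        self.stayer_consistent = np.array(
            [p.is_observed_stayer for p in self._informative], dtype=bool
        )
        if spec.has_stayer_regression:
            self.x_stayer = np.array(
                [
                    [p.baseline_covariates[name] for name in spec.stayer_covariate_names]
                    for p in self._informative
                ],
                dtype=float,
            )
        else:
            self.x_stayer = None

    # -- quadrature ---------------------------------------------------------

    def _rule(self, params: ModelParams):
        """(nodes, per-patient log-weights (n_patients, n_nodes), log pi_k)."""
        spec = self.spec
        n_pat = self.data.n_patients
        K = spec.n_quadrature_nodes
        if not spec.has_stayer_regression:
            fr = params.frailty
            # accuracy is tracked by the node-doubling diagnostic, not by
            # per-evaluation warnings (the optimiser explores extreme values)
            nodes, w = dist.quadrature_rule(fr, K, check=False)
            with np.errstate(divide="ignore"):
                logw = np.broadcast_to(np.log(w), (n_pat, w.size))
                pm = dist.point_mass(fr)
                log_pi = np.full(n_pat, -np.inf if pm == 0.0 else math.log(pm))
            return nodes, logw, log_pi
        pi_k = np.clip(stayer_probability(params.stayer_reg, self.x_stayer), 1e-12, 1 - 1e-12)
        if spec.frailty_family == "ms_invgauss":
            mover = FrailtySpec("ms_invgauss", MSInvGaussParams(pi=0.0, psi=params.shape))
            nodes, w0 = dist.quadrature_rule(mover, K, check=False)
            with np.errstate(divide="ignore"):
                logw = np.log1p(-pi_k)[:, None] + np.log(w0)[None, :]
        else:  # cp_pvf: density shape depends on patient-specific rho
            rho_k = -np.log(pi_k)
            ref = FrailtySpec("cp_pvf", CPPVFParams(rho=float(np.median(rho_k)), nu=params.shape))
            nodes, raw = dist._panel_rule_raw(ref, K)
            dens = np.empty((n_pat, nodes.size))
            for j, r in enumerate(rho_k):
                dens[j] = dist.pdf_continuous(
                    FrailtySpec("cp_pvf", CPPVFParams(rho=float(r), nu=params.shape)), nodes
                )
            with np.errstate(divide="ignore"):
                logw = np.log(raw)[None, :] + np.log(dens)
        return nodes, logw, np.log(pi_k)

    # -- log-likelihood -----------------------------------------------------

    def patient_logliks(self, params: ModelParams) -> np.ndarray:
        nodes, logw, log_pi = self._rule(params)
        cond = conditional_loglik_by_patient(
            self.data, params.baselines, params.effects, nodes
        )
        log_integral = _logsumexp_rows(logw + cond)
        with np.errstate(invalid="ignore"):
            log_stayer = np.where(self.stayer_consistent, log_pi, -np.inf)
        return np.logaddexp(log_stayer, log_integral)

    def loglik_params(self, params: ModelParams) -> float:
        ll = self.patient_logliks(params)
        bad = ~np.isfinite(ll)
        if np.any(bad):
            # debug level: optimisers routinely probe impossible parameters
            ids = [self.data.patient_ids[i] for i in np.flatnonzero(bad)[:5]]
            logger.debug("zero marginal likelihood for patient(s) %s", ids)
            return -math.inf
        return float(ll.sum())

    def loglik(self, x: np.ndarray) -> float:
        try:
            params = self.pvec.unpack(x)
        except (ValueError, OverflowError):
            return -math.inf
        return self.loglik_params(params)


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    """Row-wise logsumexp without scipy dispatch overhead; handles all -inf rows."""
    m = np.max(a, axis=1)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = m_safe + np.log(np.exp(a - m_safe[:, None]).sum(axis=1))
    return np.where(np.isfinite(m), out, -np.inf)


def patient_marginal_loglik(panel: PatientPanel, spec: ModelSpec, params) -> float:
    """Marginal log-likelihood of a single patient's panel.

    ``params`` may be a ModelParams record or a packed parameter vector.
    """
    cohort = CohortLikelihood([panel], spec)
    if isinstance(params, ModelParams):
        return cohort.loglik_params(params)
    return cohort.loglik(np.asarray(params, dtype=float))


def total_loglik(panels, spec: ModelSpec, params) -> float:
    """Sum of patient marginal log-likelihoods over a cohort."""
    cohort = CohortLikelihood(panels, spec)
    if isinstance(params, ModelParams):
        return cohort.loglik_params(params)
    return cohort.loglik(np.asarray(params, dtype=float))
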