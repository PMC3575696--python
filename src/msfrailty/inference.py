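"""Maximum-likelihood fitting, profiles, boundary tests and empirical Bayes.

Fitting maximises the marginal log-likelihood over the unconstrained
parameter vector with Nelder-Mead (restarted from perturbed optima),
and quantifies uncertainty with a finite-difference Hessian on the
transformed scale.  P(Stayer) inference uses three complementary
routes: a delta-method Wald interval, a profile log-likelihood over a
grid of stayer probabilities, and the likelihood ratio test against the
no-stayer submodel.  Because pi = 0 lies on the boundary of the
parameter space, the null distribution of that likelihood ratio
statistic is the 50:50 chi-bar-square mixture of a point mass at zero
and a chi-square with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import logging
import math

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .likelihood import CohortLikelihood, ModelParams, ModelSpec, ParameterVector, apply_constraints
from .multistate import conditional_loglik_by_patient

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "ProfileCurve",
    "EBEstimate",
    "WaldPStayer",
    "LRInterval",
    "fit",
    "default_init",
    "profile_pstayer",
    "lrt_boundary",
    "likelihood_ratio_interval",
    "empirical_bayes",
    "wald_interval_pstayer",
]

_Z95 = 1.959963984540054


@dataclass
class FitResult:
    """Converged (or flagged) maximum-likelihood fit.

    ``x`` is on the unconstrained working scale with coordinate names
    in ``names``; ``params`` the natural-scale unpacking; ``cov`` the
    working-scale covariance from the inverse negative Hessian.
    """

    spec: ModelSpec
    names: list
    x: np.ndarray
    params: ModelParams
    loglik: float
    cov: np.ndarray | None
    se: np.ndarray | None
    converged: bool
    n_iter: int
    n_restarts: int
    message: str = ""
    n_patients: int = 0
    hessian_ok: bool = True

    @property
    def aic(self) -> float:
        return 2.0 * len(self.names) - 2.0 * self.loglik

    def coordinate(self, name: str) -> tuple[float, float]:
        """(estimate, se) of one working-scale coordinate."""
        i = self.names.index(name)
        se = float(self.se[i]) if self.se is not None else math.nan
        return float(self.x[i]), se

    def intensity_ratio_table(self) -> pd.DataFrame:
        """exp(beta) with 95% Wald intervals for every covariate effect."""
        rows = []
        for i, name in enumerate(self.names):
            if not name.startswith("beta_"):
                continue
            b = float(self.x[i])
            se = float(self.se[i]) if self.se is not None else math.nan
            rows.append(
                {
                    "effect": name,
                    "intensity_ratio": math.exp(b),
                    "lower95": math.exp(b - _Z95 * se),
                    "upper95": math.exp(b + _Z95 * se),
                }
            )
        return pd.DataFrame(rows)

    def report(self) -> dict:
        out = {
            "model": self.spec.to_dict(),
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_restarts": self.n_restarts,
            "n_patients": self.n_patients,
            "message": self.message,
            "estimates_working_scale": dict(zip(self.names, map(float, self.x))),
            "se_working_scale": (
                dict(zip(self.names, map(float, self.se))) if self.se is not None else None
            ),
            "natural_scale": apply_constraints(self.spec, self.params),
        }
        if not self.spec.has_stayer_regression and self.spec.frailty_family != "gamma":
            wald = wald_interval_pstayer(self)
            out["p_stayer"] = {
                "estimate": wald.estimate,
                "lower95": wald.lower,
                "upper95": wald.upper,
                "available": wald.available,
            }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(), fh, indent=2, default=float)


def default_init(spec: ModelSpec) -> np.ndarray:
    """Generic starting point: slow baseline rates, null covariate effects,
    moderate heterogeneity and a mid-range stayer probability."""
    pvec = ParameterVector(spec)
    x = np.zeros(pvec.size)
    for i, name in enumerate(pvec.names):
        if name.startswith("log_lambda"):
            # per-year rates near 1e-2 (unit-mean schemes); relative rates for
            # the anchored scheme start at 1 except the damaged-side ones
            if spec.constraint_scheme == "anchor_lambda12":
                x[i] = math.log(5.0) if name in ("log_lambda_24", "log_lambda_34") else 0.0
            else:
                x[i] = math.log(1e-2)
        elif name == "log_theta":
            x[i] = 0.0
        elif name == "logit_pi":
            x[i] = math.log(0.25 / 0.75)
        elif name == "log_psi":
            x[i] = 0.0
        elif name == "log_rho":
            x[i] = math.log(0.7)
        elif name == "log_nu":
            x[i] = math.log(100.0)
        elif name.startswith("delta"):
            x[i] = -0.5 if name == "delta_0" else 0.0
    return x


def _neldermead(fun, x0, options, initial_simplex=None):
    opts = {"fatol": 1e-6, "xatol": 1e-5, "adaptive": True, "maxiter": 3000}
    opts.update(options or {})
    if initial_simplex is not None:
        opts["initial_simplex"] = initial_simplex
    return optimize.minimize(fun, x0, method="Nelder-Mead", options=opts)


def _maximise(negll, x0, options, n_restarts=2, rng=None):
    """Nelder-Mead with restarts from perturbed optima; returns best result."""
    rng = rng or np.random.default_rng(0)
    best = _neldermead(negll, x0, options)
    n_iter = best.nit
    used = 0
    for _ in range(n_restarts):
        # restart with a compact simplex around the incumbent optimum: cheap
        # to reconverge, still able to escape a degenerate simplex collapse
        n = len(best.x)
        simplex = np.tile(best.x, (n + 1, 1))
        simplex[1:] += 0.05 * rng.standard_normal((n, n)) / math.sqrt(n)
        simplex[1:] += np.diag(np.full(n, 0.05 * rng.choice([-1.0, 1.0])))
        res = _neldermead(negll, best.x, options, initial_simplex=simplex)
        n_iter += res.nit
        used += 1
        if res.fun < best.fun - 1e-8:
            best = res
        else:
            best.x = best.x if best.fun <= res.fun else res.x
            break
    return best, n_iter, used


def _numerical_hessian(fun, x, step=1e-4):
    """Central-difference Hessian of a scalar function."""
    n = len(x)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = step
            ej[j] = step
            if i == j:
                H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / step**2
            else:
                fpp = fun(x + ei + ej)
                fpm = fun(x + ei - ej)
                fmp = fun(x - ei + ej)
                fmm = fun(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step**2)
    return H


def fit(
    data,
    spec: ModelSpec,
    init=None,
    options=None,
    compute_cov: bool = True,
    n_restarts: int = 2,
) -> FitResult:
    """Maximise the marginal log-likelihood of a cohort.

    ``data`` is a list of PatientPanels or a prebuilt CohortLikelihood;
    ``init`` a ModelParams, a packed vector, or None for the generic
    default; ``options`` passes Nelder-Mead settings (fatol, maxiter...);
    ``n_restarts`` controls re-optimisation from perturbed optima.
    """
    cohort = data if isinstance(data, CohortLikelihood) else CohortLikelihood(data, spec)
    pvec = cohort.pvec
    if init is None:
        x0 = default_init(spec)
    elif isinstance(init, ModelParams):
        x0 = pvec.pack(init)
    else:
        x0 = np.asarray(init, dtype=float)
        if x0.shape != (pvec.size,):
            raise ValueError(f"init must have length {pvec.size}")
    if not np.all(np.isfinite(x0)):
        raise ValueError("init must be finite")

    def negll(x):
        return -cohort.loglik(x)

    best, n_iter, used = _maximise(negll, x0, options, n_restarts=n_restarts)
    converged = bool(best.success) and math.isfinite(best.fun)
    if not converged:
        logger.warning("optimiser did not converge cleanly: %s", best.message)

    cov = se = None
    hessian_ok = False
    if compute_cov and math.isfinite(best.fun):
        H = _numerical_hessian(lambda x: -negll(x), best.x)
        with np.errstate(all="ignore"):
            try:
                condition = np.linalg.cond(-H)
            except np.linalg.LinAlgError:
                condition = np.inf
            if not np.isfinite(condition) or condition > 1e12:
                logger.warning(
                    "near-singular Hessian (condition %.2e); covariance by pseudo-inverse",
                    condition,
                )
            else:
                hessian_ok = True
            cov = np.linalg.pinv(-H)
            cov = 0.5 * (cov + cov.T)
            d = np.diag(cov).copy()
            se = np.sqrt(np.where(d > 0, d, np.nan))

    return FitResult(
        spec=spec,
        names=list(pvec.names),
        x=np.asarray(best.x, float),
        params=pvec.unpack(best.x),
        loglik=-float(best.fun),
        cov=cov,
        se=se,
        converged=converged,
        n_iter=int(n_iter),
        n_restarts=used,
        message=str(best.message),
        n_patients=cohort.data.n_patients,
        hessian_ok=hessian_ok,
    )


@dataclass
class ProfileCurve:
    """Profile log-likelihood over a grid of P(Stayer) values."""

    pstayer_grid: np.ndarray
    profile_loglik: np.ndarray
    converged: np.ndarray
    max_loglik: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p_stayer": self.pstayer_grid,
                "profile_loglik": self.profile_loglik,
                "converged": self.converged,
            }
        )

    @property
    def argmax(self) -> float:
        return float(self.pstayer_grid[int(np.nanargmax(self.profile_loglik))])


def default_profile_grid(n: int = 21, lo: float = 0.001, hi: float = 0.95) -> np.ndarray:
    """Log-spaced near zero to expose flat-at-the-boundary profiles."""
    return np.geomspace(lo, hi, n)


def profile_pstayer(data, spec: ModelSpec, grid=None, init=None, options=None) -> ProfileCurve:
    """Profile the log-likelihood over fixed values of P(Stayer).

    For each grid value the stayer coordinate (logit pi, or log rho with
    rho = -log P(Stayer) for cp_pvf) is held fixed and every other
    parameter re-maximised, warm-starting each point from its
    neighbour's solution.
    """
    cohort = data if isinstance(data, CohortLikelihood) else CohortLikelihood(data, spec)
    pvec = cohort.pvec
    idx = pvec.pstayer_index
    if idx is None:
        raise ValueError("model has no single P(Stayer) parameter to profile")
    grid = default_profile_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any((grid <= 0.0) | (grid >= 1.0)) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing inside (0, 1)")
    if init is None:
        x_free = np.delete(default_init(spec), idx)
    elif isinstance(init, FitResult):
        x_free = np.delete(init.x, idx)
    else:
        init = np.asarray(init, dtype=float)
        x_free = np.delete(init, idx) if init.size == pvec.size else init
    free_idx = [i for i in range(pvec.size) if i != idx]

    lls = np.full(grid.size, np.nan)
    ok = np.zeros(grid.size, dtype=bool)
    # profile from the top of the grid downwards if warm start came from a
    # fit (typically near the MLE, which is rarely at tiny pi)
    order = range(grid.size - 1, -1, -1)
    warm = x_free.copy()
    for g in order:
        fixed = pvec.pstayer_coordinate(float(grid[g]))

        def negll(xf):
            x = np.empty(pvec.size)
            x[free_idx] = xf
            x[idx] = fixed
            return -cohort.loglik(x)

        res, _, _ = _maximise(negll, warm, options, n_restarts=1)
        lls[g] = -res.fun
        ok[g] = bool(res.success)
        if not ok[g]:
            logger.warning("profile point P(Stayer)=%.4g did not converge", grid[g])
        warm = res.x
    return ProfileCurve(grid, lls, ok)


def lrt_boundary(fit_ms: FitResult, fit_null: FitResult) -> tuple[float, float]:
    """Likelihood ratio test of pi = 0 on the boundary.

    The statistic 2(ll_ms - ll_null) is compared with the 50:50 mixture
    of a point mass at zero and chi-square(1): p = 0.5 P(chi2_1 >= T)
    for T > 0, and p = 1 at T = 0.
    """
    statistic = 2.0 * (fit_ms.loglik - fit_null.loglik)
    if statistic < -1e-6:
        logger.warning(
            "negative LRT statistic %.4g: the alternative fit has not reached "
            "its maximum; refit with better starting values",
            statistic,
        )
    statistic = max(0.0, statistic)
    p = 0.5 * stats.chi2.sf(statistic, df=1) + (0.5 if statistic == 0.0 else 0.0)
    return statistic, float(p)


@dataclass(frozen=True)
class LRInterval:
    lower: float
    upper: float
    truncated_lower: bool = False
    truncated_upper: bool = False


def likelihood_ratio_interval(
    profile: ProfileCurve, level: float = 0.95, max_loglik: float | None = None
) -> LRInterval:
    """Invert the profile deviance: {p0 : 2(max ll - profile(p0)) <= chi2_1 quantile}.

    Endpoints are interpolated linearly on the deviance between grid
    points; an interval cut off by the grid edge is flagged truncated
    (the lower edge may legitimately sit at the pi = 0 boundary).
    """
    grid = np.asarray(profile.pstayer_grid, dtype=float)
    ll = np.asarray(profile.profile_loglik, dtype=float)
    top = np.nanmax(ll)
    if max_loglik is not None:
        top = max(top, max_loglik)
    dev = 2.0 * (top - ll)
    c = stats.chi2.ppf(level, df=1)
    inside = dev <= c
    if not np.any(inside):
        raise ValueError("no grid point lies inside the interval; refine the grid")
    lo_i = int(np.argmax(inside))
    hi_i = len(grid) - 1 - int(np.argmax(inside[::-1]))

    def cross(i_out, i_in):
        # linear interpolation on the deviance: dev = c at the returned point
        d_out, d_in = dev[i_out], dev[i_in]
        w = (d_out - c) / (d_out - d_in)
        return float(grid[i_out] + (grid[i_in] - grid[i_out]) * w)

    if lo_i == 0:
        lower, trunc_lo = float(grid[0]), True
    else:
        lower, trunc_lo = cross(lo_i - 1, lo_i), False
    if hi_i == len(grid) - 1:
        upper, trunc_hi = float(grid[-1]), True
    else:
        upper, trunc_hi = cross(hi_i + 1, hi_i), False
    return LRInterval(lower, upper, trunc_lo, trunc_hi)


@dataclass(frozen=True)
class EBEstimate:
    """Empirical Bayes prediction of one patient's frailty."""

    patient_id: str
    posterior_mean_u: float
    posterior_stayer_prob: float
    implied_lambda12: float


def empirical_bayes(data, fitted: FitResult) -> list[EBEstimate]:
    """Posterior frailty summaries at the plugged-in estimates.

    The predictive distribution of u_k is proportional to
    L_k(u) f(u; theta-hat); the posterior mean shrinks towards the prior
    mean as a patient's data get less informative, and the posterior
    stayer probability is pi_k S_k over the marginal likelihood (zero
    for any patient with observed damage).
    """
    cohort = data if isinstance(data, CohortLikelihood) else CohortLikelihood(data, fitted.spec)
    params = fitted.params
    nodes, logw, log_pi = cohort._rule(params)
    cond = conditional_loglik_by_patient(cohort.data, params.baselines, params.effects, nodes)
    # work on the log scale: integrals of L(u) f(u) and u L(u) f(u)
    from scipy.special import logsumexp

    log_int = logsumexp(logw + cond, axis=1)
    with np.errstate(divide="ignore"):
        log_int_u = logsumexp(logw + cond + np.log(nodes)[None, :], axis=1)
        log_stay = np.where(cohort.stayer_consistent, log_pi, -np.inf)
    log_denom = np.logaddexp(log_stay, log_int)
    post_mean = np.exp(log_int_u - log_denom)
    post_stayer = np.exp(log_stay - log_denom)
    lam12 = params.baselines.lambda_12
    return [
        EBEstimate(
            patient_id=pid,
            posterior_mean_u=float(post_mean[i]),
            posterior_stayer_prob=float(post_stayer[i]),
            implied_lambda12=float(post_mean[i] * lam12),
        )
        for i, pid in enumerate(cohort.data.patient_ids)
    ]


@dataclass(frozen=True)
class WaldPStayer:
    estimate: float
    lower: float
    upper: float
    available: bool
    scale: str


def wald_interval_pstayer(fitted: FitResult) -> WaldPStayer:
    """Delta-method 95% interval for P(Stayer) mapped back to [0, 1].

    The interval is built on the transformed scale the parameter was
    optimised on (logit pi, or log rho with P(Stayer) = exp(-rho)) and
    mapped through the monotone link, so it respects the [0, 1] range.
    A singular Hessian leaves the interval unavailable.
    """
    pvec = ParameterVector(fitted.spec)
    name = pvec.pstayer_name
    if name is None:
        raise ValueError("model has no single P(Stayer) parameter")
    est_t, se_t = fitted.coordinate(name)
    if name == "logit_pi":
        to_p = lambda t: 1.0 / (1.0 + math.exp(-t))
        lo_t, hi_t = est_t - _Z95 * se_t, est_t + _Z95 * se_t
        est, lo, hi = to_p(est_t), to_p(lo_t), to_p(hi_t)
    else:  # log_rho; P = exp(-rho) is decreasing in rho
        est = math.exp(-math.exp(est_t))
        lo = math.exp(-math.exp(est_t + _Z95 * se_t))
        hi = math.exp(-math.exp(est_t - _Z95 * se_t))
    # a pseudo-inverse covariance reports exactly zero variance along singular
    # directions: only trust an exact zero when the full Hessian was regular
    available = (
        fitted.se is not None
        and math.isfinite(se_t)
        and (se_t > 0.0 or fitted.hessian_ok)
    )
    if not available:
        logger.warning(
            "Wald interval for P(Stayer) unavailable: Hessian singular or SE missing"
        )
        return WaldPStayer(est, math.nan, math.nan, False, name)
    if se_t == 0.0:
        return WaldPStayer(est, est, est, True, name)
    return WaldPStayer(est, lo, hi, True, name)
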