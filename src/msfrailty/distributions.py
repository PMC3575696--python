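"""Mover-stayer frailty distributions.

A patient-level frailty U scales every transition intensity of that
patient's multi-state processes.  A *stayer* has U = 0 exactly and can
never leave the initial state; a *mover* has U > 0 drawn from a
continuous distribution.  Three mixture families are supported, plus the
plain (no point mass) gamma:

``gamma``
    unit-mean Gamma(1/theta, rate 1/theta); no stayers.
``ms_gamma``
    point mass ``pi`` at zero, movers unit-mean gamma as above.
``ms_invgauss``
    point mass ``pi`` at zero, movers inverse Gaussian with mean ``mu``
    (fixed to 1 in fitted models) and shape ``psi`` (variance mu^3/psi).
``cp_pvf``
    compound Poisson member of the power-variance-function family:
    U = sum of N ~ Poisson(rho) independent Gamma(m, rate nu) terms, so
    P(U = 0) = exp(-rho).  For m = 1 the continuous density has the
    closed Bessel form  e^{-rho - nu u} sqrt(rho nu / u) I_1(2 sqrt(rho nu u)).

The stayer probability and the mover density of the compound Poisson
family share the parameter ``rho``; for the other two families the point
mass is a free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union
import math
import warnings

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "MSGammaParams",
    "MSInvGaussParams",
    "CPPVFParams",
    "FrailtySpec",
    "point_mass",
    "pdf_continuous",
    "pdf_limit_at_zero",
    "moments",
    "laplace_transform",
    "sample",
    "cdf",
    "mover_quantile",
    "quadrature_rule",
]

FAMILIES = ("gamma", "ms_gamma", "ms_invgauss", "cp_pvf")


@dataclass(frozen=True)
class MSGammaParams:
    """Mover-stayer gamma: stayer probability ``pi`` and mover variance ``theta``.

    Movers follow Gamma(1/theta, rate 1/theta), which has mean exactly 1
    and variance theta.
    """

    pi: float
    theta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi < 1.0):
            raise ValueError(f"pi must be in [0, 1), got {self.pi}")
        if not (self.theta > 0.0 and math.isfinite(self.theta)):
            raise ValueError(f"theta must be positive and finite, got {self.theta}")


@dataclass(frozen=True)
class MSInvGaussParams:
    """Mover-stayer inverse Gaussian: ``pi``, mover mean ``mu``, shape ``psi``.

    The mover density is parameterised by mean mu and shape psi with
    variance mu^3/psi; fitted models fix mu = 1, in which case the
    mixture has mean 1 - pi and variance (1 - pi)(1/psi + pi).
    """

    pi: float
    psi: float
    mu: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi < 1.0):
            raise ValueError(f"pi must be in [0, 1), got {self.pi}")
        if not (self.psi > 0.0 and math.isfinite(self.psi)):
            raise ValueError(f"psi must be positive and finite, got {self.psi}")
        if not (self.mu > 0.0 and math.isfinite(self.mu)):
            raise ValueError(f"mu must be positive and finite, got {self.mu}")


@dataclass(frozen=True)
class CPPVFParams:
    """Compound Poisson PVF: Poisson rate ``rho``, gamma rate ``nu``, shape ``m``.

    Mean rho*m/nu, variance rho*m(m+1)/nu^2, point mass exp(-rho) at
    zero.  The closed-form density requires m = 1; general m is allowed
    only for the Laplace transform and the sampler.
    """

    rho: float
    nu: float
    m: float = 1.0

    def __post_init__(self) -> None:
        if not (self.rho > 0.0 and math.isfinite(self.rho)):
            raise ValueError(f"rho must be positive and finite, got {self.rho}")
        if not (self.nu > 0.0 and math.isfinite(self.nu)):
            raise ValueError(f"nu must be positive and finite, got {self.nu}")
        if not (self.m > 0.0 and math.isfinite(self.m)):
            raise ValueError(f"m must be positive and finite, got {self.m}")


ParamsT = Union[MSGammaParams, MSInvGaussParams, CPPVFParams]

_FAMILY_PARAM_TYPE = {
    "gamma": MSGammaParams,
    "ms_gamma": MSGammaParams,
    "ms_invgauss": MSInvGaussParams,
    "cp_pvf": CPPVFParams,
}


@dataclass(frozen=True)
class FrailtySpec:
    """A frailty family together with its parameter record."""

    family: str
    params: ParamsT

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown frailty family {self.family!r}; choose from {FAMILIES}")
        expected = _FAMILY_PARAM_TYPE[self.family]
        if not isinstance(self.params, expected):
            raise ValueError(
                f"family {self.family!r} requires {expected.__name__}, "
                f"got {type(self.params).__name__}"
            )
        if self.family == "gamma" and self.params.pi != 0.0:
            raise ValueError("plain gamma frailty must have pi = 0")

    @property
    def point_mass(self) -> float:
        return point_mass(self)

    def to_dict(self) -> dict:
        d = {"family": self.family}
        d.update(vars(self.params))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FrailtySpec":
        d = dict(d)
        family = d.pop("family")
        try:
            params = _FAMILY_PARAM_TYPE[family](**d)
        except KeyError:
            raise ValueError(f"unknown frailty family {family!r}") from None
        return cls(family, params)


def _as_spec(spec_or_params) -> FrailtySpec:
    if isinstance(spec_or_params, FrailtySpec):
        return spec_or_params
    if isinstance(spec_or_params, CPPVFParams):
        return FrailtySpec("cp_pvf", spec_or_params)
    if isinstance(spec_or_params, MSInvGaussParams):
        return FrailtySpec("ms_invgauss", spec_or_params)
    if isinstance(spec_or_params, MSGammaParams):
        return FrailtySpec("ms_gamma" if spec_or_params.pi > 0 else "gamma", spec_or_params)
    raise TypeError(f"expected FrailtySpec or parameter record, got {type(spec_or_params)}")


def point_mass(spec: FrailtySpec) -> float:
    """P(U = 0): the stayer probability implied by the frailty distribution."""
    spec = _as_spec(spec)
    if spec.family == "cp_pvf":
        return math.exp(-spec.params.rho)
    return spec.params.pi


def _mover_dist(spec: FrailtySpec):
    """Frozen scipy distribution of the continuous (mover) component.

    Used for sampling; the density/CDF/quantile hot paths below use direct
    special-function formulas because freezing a scipy distribution is
    costly inside optimisation loops.
    """
    p = spec.params
    if spec.family in ("gamma", "ms_gamma"):
        a = 1.0 / p.theta
        return stats.gamma(a, scale=p.theta)
    if spec.family == "ms_invgauss":
        # scipy invgauss(mu_s, scale=s): mean mu_s*s, shape parameter s
        return stats.invgauss(p.mu / p.psi, scale=p.psi)
    raise ValueError(f"no scipy mover distribution for family {spec.family!r}")


def _mover_pdf(spec: FrailtySpec, u: np.ndarray) -> np.ndarray:
    """Density of the mover component (normalised to integrate to 1)."""
    p = spec.params
    if spec.family in ("gamma", "ms_gamma"):
        a = 1.0 / p.theta
        with np.errstate(divide="ignore"):
            return np.exp(
                (a - 1.0) * np.log(u) - u / p.theta - special.gammaln(a) - a * math.log(p.theta)
            )
    if spec.family == "ms_invgauss":
        return np.sqrt(p.psi / (2.0 * np.pi * u**3)) * np.exp(
            -p.psi * (u - p.mu) ** 2 / (2.0 * p.mu**2 * u)
        )
    raise ValueError(f"no mover density for family {spec.family!r}")


def _mover_cdf(spec: FrailtySpec, u: np.ndarray) -> np.ndarray:
    p = spec.params
    if spec.family in ("gamma", "ms_gamma"):
        return special.gammainc(1.0 / p.theta, u / p.theta)
    if spec.family == "ms_invgauss":
        with np.errstate(divide="ignore"):
            r = np.sqrt(p.psi / u)
            z = u / p.mu
            return special.ndtr(r * (z - 1.0)) + np.exp(2.0 * p.psi / p.mu) * special.ndtr(
                -r * (z + 1.0)
            )
    raise ValueError(f"no mover CDF for family {spec.family!r}")


def _mover_ppf(spec: FrailtySpec, q: np.ndarray) -> np.ndarray:
    p = spec.params
    if spec.family in ("gamma", "ms_gamma"):
        return p.theta * special.gammaincinv(1.0 / p.theta, q)
    if spec.family == "ms_invgauss":
        return stats.invgauss.ppf(q, p.mu / p.psi, scale=p.psi)
    raise ValueError(f"no mover quantile for family {spec.family!r}")


def pdf_continuous(spec: FrailtySpec, u) -> np.ndarray:
    """Density of the continuous part at u > 0; integrates to 1 - point_mass.

    For cp_pvf (m = 1) uses the Bessel closed form with exponential
    scaling of I_1 so that large arguments 2 sqrt(rho nu u) do not
    overflow.
    """
    spec = _as_spec(spec)
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or not np.all(np.isfinite(u)):
        raise ValueError("pdf_continuous requires u > 0 and finite")
    p = spec.params
    if spec.family == "cp_pvf":
        if p.m != 1.0:
            raise ValueError("closed-form cp_pvf density requires m = 1")
        h = 2.0 * np.sqrt(p.rho * p.nu * u)
        # I1(h) = i1e(h) * e^h; fold e^h into the exponent
        return np.sqrt(p.rho * p.nu / u) * special.i1e(h) * np.exp(h - p.rho - p.nu * u)
    return (1.0 - p.pi) * _mover_pdf(spec, u)


def pdf_limit_at_zero(params: CPPVFParams) -> float:
    """Finite u -> 0 limit of the continuous cp_pvf density (m = 1 only).

    Only the single-event term of the Poisson mixture survives at the
    origin, giving rho * nu * exp(-rho).
    """
    if not isinstance(params, CPPVFParams):
        raise TypeError("pdf_limit_at_zero is defined for CPPVFParams")
    if params.m != 1.0:
        raise ValueError("the density limit is available only for m = 1")
    return params.rho * params.nu * math.exp(-params.rho)


def moments(spec: FrailtySpec) -> tuple[float, float]:
    """(mean, variance) of the full mixture distribution."""
    spec = _as_spec(spec)
    p = spec.params
    if spec.family in ("gamma", "ms_gamma"):
        return 1.0 - p.pi, (1.0 - p.pi) * (p.theta + p.pi)
    if spec.family == "ms_invgauss":
        mean = (1.0 - p.pi) * p.mu
        # E U^2 = (1-pi)(mu^2 + mu^3/psi); var = E U^2 - mean^2
        var = (1.0 - p.pi) * (p.mu**2 + p.mu**3 / p.psi) - mean**2
        return mean, var
    if spec.family == "cp_pvf":
        return p.rho * p.m / p.nu, p.rho * p.m * (p.m + 1.0) / p.nu**2
    raise ValueError(f"unknown family {spec.family!r}")


def laplace_transform(params, s) -> np.ndarray:
    """E[exp(-sU)] for s >= 0.

    For cp_pvf: exp(-rho [1 - (nu/(nu+s))^m]), valid for any m > 0.
    Also defined for the gamma and inverse Gaussian mixtures, which is
    convenient for cross-checks.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0.0):
        raise ValueError("laplace_transform requires s >= 0")
    spec = _as_spec(params)
    p = spec.params
    if spec.family == "cp_pvf":
        return np.exp(-p.rho * (1.0 - (p.nu / (p.nu + s)) ** p.m))
    if spec.family in ("gamma", "ms_gamma"):
        return p.pi + (1.0 - p.pi) * (1.0 + p.theta * s) ** (-1.0 / p.theta)
    if spec.family == "ms_invgauss":
        mover = np.exp((p.psi / p.mu) * (1.0 - np.sqrt(1.0 + 2.0 * p.mu**2 * s / p.psi)))
        return p.pi + (1.0 - p.pi) * mover
    raise ValueError(f"unknown family {spec.family!r}")


def sample(spec: FrailtySpec, n: int, seed) -> np.ndarray:
    """Draw n frailty values; stayers appear as exact zeros.

    cp_pvf draws N ~ Poisson(rho) then the sum of N Gamma(m, rate nu)
    terms (a single Gamma(mN, rate nu) draw); the mover-stayer families
    draw a Bernoulli(pi) stayer indicator then the mover component.
    """
    spec = _as_spec(spec)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = spec.params
    if spec.family == "cp_pvf":
        counts = rng.poisson(p.rho, size=n)
        return rng.gamma(shape=p.m * counts, scale=1.0 / p.nu)
    stayer = rng.random(n) < p.pi
    movers = _mover_dist(spec).rvs(size=n, random_state=rng)
    return np.where(stayer, 0.0, movers)


def _cp_poisson_terms(rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Poisson(rho) pmf over n = 1, 2, ... up to a negligible tail."""
    n_max = int(max(40, rho + 12.0 * math.sqrt(rho) + 20))
    n = np.arange(1, n_max + 1)
    pmf = np.exp(n * math.log(rho) - rho - special.gammaln(n + 1.0))
    return n, pmf


def cdf(spec: FrailtySpec, u) -> np.ndarray:
    """Mixture CDF: point_mass + integral of the continuous part over (0, u]."""
    spec = _as_spec(spec)
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0):
        raise ValueError("cdf requires u >= 0")
    pm = point_mass(spec)
    p = spec.params
    if spec.family == "cp_pvf":
        # Poisson mixture of Gamma(mn, nu) CDFs, n >= 1
        n, pmf = _cp_poisson_terms(p.rho)
        cont = special.gammainc(p.m * n, p.nu * u[..., None]) @ pmf
        return pm + cont
    return pm + (1.0 - pm) * _mover_cdf(spec, u)


def mover_quantile(spec: FrailtySpec, q) -> np.ndarray:
    """Quantile function of the continuous (mover) component alone."""
    spec = _as_spec(spec)
    q = np.asarray(q, dtype=float)
    if np.any((q < 0.0) | (q > 1.0)):
        raise ValueError("quantile levels must lie in [0, 1]")
    if spec.family != "cp_pvf":
        return _mover_ppf(spec, q)
    p = spec.params
    pm = point_mass(spec)

    def mover_cdf(x):
        return (cdf(spec, x) - pm) / (1.0 - pm)

    # bracket: mover mean / (1-pm) bounds scale; expand upper until covered
    mean_mover = (p.rho * p.m / p.nu) / (1.0 - pm)
    out = np.empty_like(q)
    for i, qi in np.ndenumerate(q):
        if qi <= 0.0:
            out[i] = 0.0
            continue
        hi = max(mean_mover, 1.0 / p.nu)
        while mover_cdf(hi) < qi:
            hi *= 2.0
            if hi > 1e12:
                out[i] = np.inf
                break
        else:
            out[i] = optimize.brentq(
                lambda x: mover_cdf(x) - qi, 0.0, hi, xtol=1e-12, rtol=1e-8
            )
            continue
    return out


# Mover-mass breakpoints for the composite Gauss-Legendre panels used on the
# smooth (non-gamma) mover densities; the last panel ends at the 1 - 1e-8
# mover quantile.
_PANEL_PROBS_IG = np.array([1e-12, 0.05, 0.3, 0.7, 0.95, 1.0 - 1e-8])
_PANEL_PROBS_CP = np.array([0.0, 0.1, 0.5, 0.9, 1.0 - 1e-8])


def _panel_rule_raw(spec: FrailtySpec, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Panel nodes with raw Gauss-Legendre weights (density not applied).

    The inverse Gaussian integrates on the log scale, where its sharp
    peak and heavy tail both become polynomially tame; the compound
    Poisson density (m = 1) is finite at the origin and integrates on
    the linear scale from 0.  Raw weights include the Jacobian, so
    weights for density integrals are raw * pdf_continuous(node).
    """
    if spec.family == "ms_invgauss":
        edges = np.log(mover_quantile(spec, _PANEL_PROBS_IG))
        log_scale = True
    elif spec.family == "cp_pvf":
        edges = mover_quantile(spec, _PANEL_PROBS_CP)
        edges[0] = 0.0
        log_scale = False
    elif spec.family in ("gamma", "ms_gamma"):
        # used only for near-degenerate movers (theta small, shape large),
        # where the density is a narrow smooth peak near 1
        edges = mover_quantile(spec, _PANEL_PROBS_IG)
        log_scale = False
    else:
        raise ValueError(f"panel rule not used for family {spec.family!r}")
    n_panels = len(edges) - 1
    per = max(4, int(np.ceil(n_nodes / n_panels)))
    gx, gw = np.polynomial.legendre.leggauss(per)
    nodes_l, raw_l = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        half = 0.5 * (hi - lo)
        y = lo + half * (gx + 1.0)
        if log_scale:
            u = np.exp(y)
            nodes_l.append(u)
            raw_l.append(half * gw * u)  # Jacobian du = u dy
        else:
            nodes_l.append(y)
            raw_l.append(half * gw)
    return np.concatenate(nodes_l), np.concatenate(raw_l)


def quadrature_rule(
    spec: FrailtySpec, n_nodes: int = 40, check: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights approximating integrals against the mover density.

    sum_i w_i g(x_i) ~ integral of g(u) * f_cont(u) du over (0, inf), so
    a constant integrand recovers 1 - point_mass and the identity
    recovers the mover-component mean.

    Gamma movers use generalized Gauss-Laguerre, which is exact for the
    gamma weight even when the density diverges at the origin (theta > 1).
    The inverse Gaussian and compound Poisson movers are smooth, and use
    Gauss-Legendre panels between mover quantiles (log scale for the
    inverse Gaussian) so that nodes track the probability mass whatever
    the peak/tail scale ratio.
    """
    spec = _as_spec(spec)
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    pm = point_mass(spec)
    p = spec.params

    if spec.family in ("gamma", "ms_gamma") and p.theta >= 1e-2:
        a = 1.0 / p.theta
        x, w = special.roots_genlaguerre(n_nodes, a - 1.0)
        nodes = p.theta * x
        weights = (1.0 - p.pi) * w / special.gamma(a)
    else:
        nodes, raw = _panel_rule_raw(spec, n_nodes)
        weights = raw * pdf_continuous(spec, nodes)

    total = weights.sum()
    if check and abs(total - (1.0 - pm)) > 1e-6:
        warnings.warn(
            f"quadrature normalization error {abs(total - (1.0 - pm)):.2e} "
            f"with {len(nodes)} nodes; increase n_nodes",
            RuntimeWarning,
        )
    return nodes, weights
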