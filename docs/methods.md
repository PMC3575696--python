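# Methods

## Model

Each joint location of a patient follows a continuous-time progressive
four-state process (1 = no damage, 2 = left damaged, 3 = right damaged,
4 = both). Allowed transitions are 1→2, 1→3, 2→4 and 3→4; damage is
irreversible and the two sides cannot change state simultaneously, so
1→4 has no intensity (an observed 1→4 jump in panel data arises from a
latent 1→2→4 or 1→3→4 path within one interval). State 4 is absorbing.

Intensities multiply a patient-level frailty, baseline rates and
covariate effects:

    q_ij(t) = u_k · λ0_ij · exp(β_ij' z(t)).

Locations are conditionally independent given u_k. Covariates are
visit-level activity indicators: tenderness only, effusion (with or
without tenderness; the two indicators are mutually exclusive), current
activity in the opposite joint, and ever-active ("past activity") flags
for both sides. For transitions out of state 1 five coefficients apply;
once the opposite joint is damaged, three. Coefficients and baselines are
shared across locations and across mirrored transitions (1→2 with 1→3,
2→4 with 3→4), as a single reported set. Covariates are held at their
interval-start values (piecewise-constant panel convention); the
synthetic-data generator freezes covariates the same way, so estimation
on simulated cohorts is unbiased by construction.

## Frailty families

All three mover–stayer distributions put probability P(U = 0) on exact
zero (stayers) and a continuous density on the movers:

* **ms_gamma** — stayer probability π, movers Gamma(1/θ, rate 1/θ) with
  mean exactly 1 and variance θ. Mixture mean 1−π, variance (1−π)(θ+π).
* **ms_invgauss** — stayer probability π, movers inverse Gaussian
  parameterised by mean μ (fixed at 1 in fitted models) and shape ψ, with
  variance μ³/ψ. With μ = 1 the mixture has mean 1−π and variance
  (1−π)(1/ψ+π), matching the mover–stayer gamma with θ = 1/ψ; the density
  shape differs (it vanishes at the origin).
* **cp_pvf** — the compound Poisson member of the power-variance-function
  family with gamma shape m = 1: U is a sum of N ~ Poisson(ρ) independent
  Exp(ν) terms, P(U = 0) = exp(−ρ), mean ρ/ν, variance 2ρ/ν². The
  continuous part has the closed Bessel form
  e^{−ρ−νu} √(ρν/u) I₁(2√(ρνu)) with finite limit ρνexp(−ρ) as u → 0.
  I₁ is evaluated in exponentially scaled form (`i1e`) because its
  argument 2√(ρνu) overflows `i1` for plausible parameter values. General
  m is supported only by the Laplace transform
  exp(−ρ[1 − (ν/(ν+s))^m]) and the sampler; the density used in fitting
  is the m = 1 closed form throughout.

The key structural contrast: the gamma mover density diverges at the
origin whenever θ > 1, so slow movers and stayers compete for the same
probability mass and π is poorly identified; the inverse Gaussian and
compound Poisson mover densities are bounded near 0, and for the compound
Poisson the same parameter ρ controls both the point mass and the mover
shape, which further stabilises estimation of P(Stayer).

## Identifiability constraints

Frailty scale and baseline intensities trade off exactly, so one of them
must be pinned:

* `unit_mover_mean` (gamma and inverse Gaussian families): the mover
  component has mean 1; baselines are per-year rates.
* `anchor_lambda12` (compound Poisson): forcing mean 1 would impose
  ρ = ν, so instead λ0_12 ≡ 1 on the working scale and the other
  baselines are relative to it; the reported baseline i→j intensity is
  (ρ/ν)·λ_ij(relative), the expected intensity at covariate zero. The
  inverse Gaussian column is reported analogously as (1−π)·λ.

## Likelihood and quadrature

A patient's marginal likelihood is π_k·S_k + ∫ L_k(u) f_cont(u) du, with
S_k = 1 iff every observed state is 1. Interval transition probabilities
given u use the acyclic closed form (exponential survival plus a
convolution along the 1→2→4 / 1→3→4 paths, written with the stable
φ(x) = (1−e^{−x})/x so near-equal competing rates need no special case);
`interval_transition_matrix` additionally falls back to `scipy.linalg.expm`
when rate differences are below 1e−9 relative. The whole cohort's
conditional log-likelihoods are evaluated for all quadrature nodes at
once (one outer product covers every survival interval; only observed
transitions need the convolution terms), then combined by row-wise
logsumexp, so one likelihood evaluation on a 200-patient × 14-location
cohort costs a few tens of milliseconds.

The frailty integral uses fixed-size family-specific rules
(`n_quadrature_nodes`, default 64):

* gamma movers: generalized Gauss–Laguerre, exact for the gamma weight
  even when the density diverges at the origin. For θ < 0.01 the Laguerre
  weights overflow and the rule switches to quantile panels (the density
  is then a narrow smooth peak near 1).
* inverse Gaussian movers: composite Gauss–Legendre between mover
  quantiles **on the log scale**, where both the sharp peak and the heavy
  tail become polynomially tame.
* compound Poisson movers: composite Gauss–Legendre between mover
  quantiles on the linear scale from 0 (the density is finite at the
  origin), with the mover quantiles obtained by bisecting the
  Poisson-mixture CDF.

At the defaults, rule normalisation errors are ≲1e−6 and doubling the
node count changes a fitted cohort log-likelihood by ≪1e−4 (the CLI logs
this node-doubling diagnostic after each fit). Node counts beyond ~256
are not useful: the Laguerre weight computation itself degrades first.
With a covariate-dependent stayer probability the compound Poisson mover
density depends on the patient's own ρ_k; nodes are then placed using the
cohort-median ρ and per-patient densities are evaluated on them.

## Estimation and inference

The unconstrained parameter vector carries baselines and positive frailty
parameters on the log scale and π on the logit scale. Maximisation is
Nelder–Mead (adaptive simplex) with restarts from a compact simplex
around the incumbent optimum; convergence when the simplex function
spread falls below `fatol` (default 1e−6). The covariance is the
pseudo-inverse of the negative central-difference Hessian (step 1e−4 on
the working scale) with a condition-number warning; intensity-ratio
intervals are exp(β̂ ± 1.96 se).

P(Stayer) inference has three routes:

* **Wald**: delta method on the transformed scale (logit π, or log ρ with
  P = exp(−ρ)), mapped back through the monotone link so the interval
  respects [0, 1]. The log ρ scale was chosen for the compound Poisson
  because ρ is the optimised coordinate and positive by construction. The
  interval is reported unavailable when the stayer coordinate's variance
  is not estimable (singular Hessian) — the situation the mover–stayer
  gamma family produces on real-scale data.
* **Profile likelihood**: P(Stayer) fixed on a grid (default 21 points,
  log-spaced on [0.001, 0.95] to expose boundary pathologies), all other
  parameters re-maximised with warm starts between neighbouring points;
  the 95% likelihood-ratio interval inverts the profile deviance at the
  χ²₁ 0.95 quantile with linear interpolation, allowing 0 as a boundary
  endpoint.
* **Boundary LRT**: the null π = 0 lies on the parameter-space boundary,
  so 2·Δll is referred to the 50:50 mixture of a point mass at zero and
  χ²₁ (p = 0.5·P(χ²₁ ≥ T) for T > 0, p = 1 at T = 0). The π = 0 submodel
  is expressed by `ModelSpec(fix_pstayer_zero=True)`.

Empirical Bayes prediction evaluates the posterior of u_k under the
plugged-in estimates: posterior mean ∫u L_k(u) f(u) du / L_k and posterior
stayer probability π_k S_k / L_k (exactly 0 once any damage is observed);
the implied baseline 1→2 intensity û_k·λ̂0_12 makes patients comparable
across families with different frailty scales.

## Synthetic-data generator

The generator is the package's test bed and mirrors the cohort design the
model was built for. Defaults: 14 joint locations; visit gaps uniform on
[0.5, 1] years; follow-up exponential with mean 6.9 years truncated to
[0.25, 28] (the first post-entry visit is always kept, so every patient
has ≥2 visits); per-side activity evolving as a symmetric three-state
chain at visit epochs with persistence 0.7 and a uniform stationary
start (no activity dynamics are reported for the real cohort — only the
regression role of activity matters for testing); damage simulated in
continuous time between visits by competing exponentials with covariates
frozen at interval start; only visit-time states recorded.
`scenario_from_table1` loads the published fitted values of each frailty
family as simulation truths, mapping reported baselines back to the
working scale (dividing by 1−π for the inverse Gaussian, anchoring
λ0_12 = 1 for the compound Poisson). Simulating 510 patients at the
compound Poisson truth reproduces the ~71% observed-stayer fraction of
the real cohort (72% at seed 1).

What the generator does **not** emulate: informative visit times or
dropout, left truncation by unknown disease duration at clinic entry,
activity–damage feedback (activity evolves independently of the damage
state), and any between-location heterogeneity of rates. Passing
recovery tests therefore show the estimator is correct under the model's
own assumptions, not that the model is correct for registry data.

## Scaled study designs in the test suite

The suite's long-running studies use sizes chosen as desk-scale versions
of the full analysis: parameter recovery uses single fixed-seed cohorts
of 200 patients × 14 locations per family; Wald coverage uses 12
replicates of 100 patients × 6 locations without activity covariates;
the null calibration of the boundary test uses 200 replicates of 30
patients × 4 locations with no activity covariates in either the
generator or the fitted model, so each replicate fits only baselines and
frailty parameters. All replicate seeds derive from base seed 1.

Two known limitations surface in these studies. First, at 200 patients
the mover–stayer gamma profile on no-stayer (gamma frailty) data is so
flat in π that its maximiser is essentially arbitrary over [0, ~0.3]:
π = 0 always lies inside the 95% likelihood-ratio region, but the profile
maximum lands at the boundary in only a minority of realisations — the
non-identifiability itself, not a boundary maximum, is the reproducible
phenomenon. Second, the boundary LRT at this replicate size is mildly
conservative (observed rejection rates a few percent below nominal),
consistent with the mover–stayer gamma's weak identification; the
chi-bar-square reference is asymptotic.

## Numerical choices

* Transition probabilities are clipped to [0, 1] before logs; impossible
  observed transitions give −inf log-likelihood and propagate as zero
  patient likelihood with the patient id logged.
* Nelder–Mead explores extreme parameters; quadrature built inside the
  likelihood skips the normalisation warning (accuracy is audited by the
  node-doubling diagnostic instead).
* The stayer-probability links: `cloglog_on_pi`
  (log(−log(1−π)) = δ'x, the default) and `loglog_on_pi`
  (log(−log π) = δ'x, equivalent to ρ_k = exp(δ'x) for the compound
  Poisson). Both are implemented because either convention appears in
  applied work; the default follows the form stated for the fitted model.
* Stayer covariates are standardized (cohort mean/SD) at data
  preparation (`prepare_stayer_covariate`), with the baseline value taken
  from the first visit and imputed from the earliest later visit when
  missing; patients with no value anywhere are dropped and counted.
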