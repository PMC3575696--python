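"""Fit the compound Poisson mover-stayer model and profile P(Stayer).

Simulates a cohort at known truth, maximises the marginal likelihood
(activity covariates off to keep the example compact), reports the stayer
probability with its Wald interval, and inverts the profile likelihood
into a likelihood-ratio interval.  Takes a couple of minutes.
"""

import numpy as np

from msfrailty import (
    ModelSpec,
    fit,
    likelihood_ratio_interval,
    profile_pstayer,
    scenario_from_table1,
    simulate_cohort,
    wald_interval_pstayer,
)
from msfrailty.simulate import SimulationScenario

TRUTH = np.exp(-0.46)  # 0.631

base = scenario_from_table1("cp_pvf", n_patients=200, seed=1)
scenario = SimulationScenario(
    n_patients=200,
    frailty=base.frailty,
    baselines=base.baselines,
    n_locations=10,
    seed=1,
)
panels = simulate_cohort(scenario)

spec = ModelSpec("cp_pvf", with_activity_covariates=False, n_quadrature_nodes=24)
result = fit(panels, spec, options={"fatol": 1e-5, "xatol": 1e-3, "maxiter": 2000})

print(f"converged: {result.converged} (loglik {result.loglik:.2f})")
wald = wald_interval_pstayer(result)
print(
    f"P(Stayer): estimate {wald.estimate:.3f}, "
    f"95% Wald interval ({wald.lower:.3f}, {wald.upper:.3f}); truth {TRUTH:.3f}"
)

grid = np.array([0.40, 0.50, 0.58, 0.65, 0.72, 0.80, 0.90])
curve = profile_pstayer(panels, spec, grid=grid, init=result,
                        options={"fatol": 1e-5, "xatol": 3e-3, "maxiter": 1000})
interval = likelihood_ratio_interval(curve, max_loglik=result.loglik)
print(f"profile argmax {curve.argmax:.2f}; "
      f"95% likelihood-ratio interval ({interval.lower:.3f}, {interval.upper:.3f})")
print("The stayer fraction is identifiable under the compound Poisson family\n"
      "because its mover density is finite at the origin; both intervals are\n"
      "subject to ordinary sampling variability around the truth.")
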