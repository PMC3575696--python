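"""Mover-stayer frailty families: point masses, densities, moments.

Builds the three mixture distributions at the fitted values of the paired
hand-joint damage analysis and prints the quantities that distinguish them:
the stayer probability P(U = 0), the behaviour of the mover density near
zero, and the first two moments.
"""

import numpy as np

from msfrailty import (
    CPPVFParams,
    FrailtySpec,
    MSGammaParams,
    MSInvGaussParams,
    moments,
    pdf_continuous,
    pdf_limit_at_zero,
    point_mass,
)

specs = {
    "mover-stayer gamma": FrailtySpec("ms_gamma", MSGammaParams(pi=0.042, theta=3.57)),
    "mover-stayer inverse Gaussian": FrailtySpec(
        "ms_invgauss", MSInvGaussParams(pi=0.334, psi=0.33)
    ),
    "compound Poisson PVF": FrailtySpec("cp_pvf", CPPVFParams(rho=0.46, nu=176.43)),
}

for name, spec in specs.items():
    mean, var = moments(spec)
    dens_small = float(pdf_continuous(spec, 1e-4))
    print(f"{name}:")
    print(f"  P(Stayer) = {point_mass(spec):.3f}")
    print(f"  mixture mean = {mean:.4f}, variance = {var:.4f}")
    print(f"  mover density at u = 1e-4: {dens_small:.4g}")

cp = specs["compound Poisson PVF"].params
print(
    f"\nCP-PVF density limit at u -> 0: rho*nu*exp(-rho) = {pdf_limit_at_zero(cp):.2f}"
)
print(
    "The gamma mover density diverges at the origin (slow movers are\n"
    "indistinguishable from stayers), while the CP-PVF density stays finite:\n"
    "this is why the stayer fraction is identifiable under the CP-PVF family\n"
    "but poorly identified under the mover-stayer gamma."
)
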