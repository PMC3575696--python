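import numpy as np
import pytest

from msfrailty import (
    BaselineIntensities,
    CovariateEffects,
    CPPVFParams,
    FrailtySpec,
    LocationVisit,
    MSGammaParams,
    MSInvGaussParams,
    PatientPanel,
)

BASE_SEED = 1


@pytest.fixture
def cp_table():
    """Compound Poisson frailty at the fitted values of the damage analysis."""
    return FrailtySpec("cp_pvf", CPPVFParams(rho=0.46, nu=176.43))


@pytest.fixture
def family_grid():
    """A spread of parameter settings across all three mixture families."""
    specs = []
    for pi, theta in [(0.0, 3.81), (0.2, 0.5), (0.5, 2.0)]:
        fam = "ms_gamma" if pi > 0 else "gamma"
        specs.append(FrailtySpec(fam, MSGammaParams(pi=pi, theta=theta)))
    for pi, psi in [(0.334, 0.33), (0.1, 2.0)]:
        specs.append(FrailtySpec("ms_invgauss", MSInvGaussParams(pi=pi, psi=psi)))
    for rho, nu in [(0.46, 176.43), (1.0, 1.0), (2.5, 8.0)]:
        specs.append(FrailtySpec("cp_pvf", CPPVFParams(rho=rho, nu=nu)))
    return specs


def make_visits(times_states, dt_activity=None):
    """Visit list from (time, state) pairs; no activity unless given."""
    visits = []
    ever = False
    for i, (t, s) in enumerate(times_states):
        act = 0 if dt_activity is None else dt_activity[i]
        ever = ever or act != 0
        visits.append(
            LocationVisit(
                time=t,
                state=s,
                left_activity=act,
                right_activity=0,
                left_ever_active=ever,
                right_ever_active=False,
            )
        )
    return visits


@pytest.fixture
def quiet_panel():
    """A two-location patient who never leaves state 1."""
    return PatientPanel(
        patient_id="quiet",
        locations={
            1: make_visits([(0.0, 1), (1.0, 1), (2.0, 1)]),
            2: make_visits([(0.0, 1), (1.1, 1)]),
        },
    )


@pytest.fixture
def damaged_panel():
    """A patient whose first location progresses 1 -> 2 -> 4."""
    return PatientPanel(
        patient_id="damaged",
        locations={
            1: make_visits([(0.0, 1), (1.0, 2), (2.5, 4)]),
            2: make_visits([(0.0, 1), (1.0, 1), (2.5, 1)]),
        },
    )
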