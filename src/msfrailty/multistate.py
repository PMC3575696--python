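"""Four-state paired-joint damage process.

Each joint location pairs a left and a right joint and occupies one of
four states: 1 = neither damaged, 2 = left only, 3 = right only,
4 = both damaged.  Damage is irreversible and the two sides cannot be
damaged at the same instant, so the only allowed transitions are
1->2, 1->3, 2->4 and 3->4, with state 4 absorbing.

The intensity of the i->j transition for patient k is

    q_ij(t) = u_k * lambda0_ij * exp(beta_ij' z(t))

where u_k is the patient's frailty, lambda0_ij a baseline rate per year
and z(t) visit-level activity covariates.  The "transitive" joint is
the one undergoing the transition to damage; the "opposite" joint is
its mirror image on the other hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math

import numpy as np
from scipy.linalg import expm

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionStructure",
    "BaselineIntensities",
    "CovariateEffects",
    "LocationVisit",
    "PatientPanel",
    "ACTIVITY_NONE",
    "ACTIVITY_TENDER",
    "ACTIVITY_EFFUSION",
    "build_intensity_matrix",
    "transition_rates",
    "interval_transition_matrix",
    "location_conditional_loglik",
    "patient_conditional_lik",
]

ACTIVITY_NONE = 0
ACTIVITY_TENDER = 1
ACTIVITY_EFFUSION = 2

_ACTIVITY_LABELS = {"none": 0, "tender": 1, "effusion": 2}

#: observed state pairs consistent with the irreversible structure
VALID_OBSERVED_PAIRS = frozenset(
    {(1, 1), (1, 2), (1, 3), (1, 4), (2, 2), (2, 4), (3, 3), (3, 4), (4, 4)}
)


@dataclass(frozen=True)
class TransitionStructure:
    """The progressive four-state structure; state 4 is absorbing."""

    states: tuple = (1, 2, 3, 4)
    allowed: tuple = ((1, 2), (1, 3), (2, 4), (3, 4))
    absorbing: tuple = (4,)

    def observed_pair_valid(self, s_from: int, s_to: int) -> bool:
        return (s_from, s_to) in VALID_OBSERVED_PAIRS


STRUCTURE = TransitionStructure()


@dataclass(frozen=True)
class BaselineIntensities:
    """Baseline rates per year for the four allowed transitions."""

    lambda_12: float
    lambda_13: float
    lambda_24: float
    lambda_34: float

    def __post_init__(self) -> None:
        for name in ("lambda_12", "lambda_13", "lambda_24", "lambda_34"):
            v = getattr(self, name)
            if not (v >= 0.0 and math.isfinite(v)):
                raise ValueError(f"{name} must be a finite nonnegative rate, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda_12, self.lambda_13, self.lambda_24, self.lambda_34])


@dataclass(frozen=True)
class CovariateEffects:
    """Log-intensity-ratio coefficients shared across locations and mirrored transitions.

    ``beta_nodamage`` (applied to 1->2 and 1->3), in order:
      tenderness only in the transitive joint, effusion (with or without
      tenderness) in the transitive joint, current activity in the
      opposite joint, transitive joint ever active, opposite joint ever
      active.
    ``beta_oppdamaged`` (applied to 2->4 and 3->4), in order:
      tenderness only in the transitive joint, effusion in the
      transitive joint, transitive joint ever active.
    """

    beta_nodamage: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    beta_oppdamaged: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.beta_nodamage) != 5 or len(self.beta_oppdamaged) != 3:
            raise ValueError("beta_nodamage needs 5 coefficients, beta_oppdamaged needs 3")
        if not all(math.isfinite(b) for b in (*self.beta_nodamage, *self.beta_oppdamaged)):
            raise ValueError("covariate effects must be finite")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.beta_nodamage, float), np.asarray(self.beta_oppdamaged, float)


def _norm_activity(a) -> int:
    if isinstance(a, str):
        try:
            return _ACTIVITY_LABELS[a]
        except KeyError:
            raise ValueError(f"unknown activity label {a!r}") from None
    a = int(a)
    if a not in (0, 1, 2):
        raise ValueError(f"activity code must be 0 (none), 1 (tender) or 2 (effusion), got {a}")
    return a


@dataclass(frozen=True)
class LocationVisit:
    """One clinic visit of one joint location.

    Activity codes: 0 = none, 1 = tenderness only, 2 = effusion (with or
    without tenderness); string labels 'none'/'tender'/'effusion' are
    also accepted.
    """

    time: float
    state: int
    left_activity: int = 0
    right_activity: int = 0
    left_ever_active: bool = False
    right_ever_active: bool = False

    def __post_init__(self) -> None:
        if not (self.time >= 0.0 and math.isfinite(self.time)):
            raise ValueError(f"visit time must be finite and >= 0, got {self.time}")
        if self.state not in (1, 2, 3, 4):
            raise ValueError(f"state must be 1-4, got {self.state}")
        object.__setattr__(self, "left_activity", _norm_activity(self.left_activity))
        object.__setattr__(self, "right_activity", _norm_activity(self.right_activity))


def _activity_design(visit: LocationVisit) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Design vectors (z12, z13, z24, z34) at this visit's covariate values.

    Transitive side: left for 1->2 and 3->4, right for 1->3 and 2->4.
    """

    def side(act, ever):
        tender = 1.0 if act == ACTIVITY_TENDER else 0.0
        effus = 1.0 if act == ACTIVITY_EFFUSION else 0.0
        active = 1.0 if act != ACTIVITY_NONE else 0.0
        return tender, effus, active, (1.0 if ever else 0.0)

    lt, le, la, lev = side(visit.left_activity, visit.left_ever_active)
    rt, re_, ra, rev = side(visit.right_activity, visit.right_ever_active)
    z12 = np.array([lt, le, ra, lev, rev])  # left transitive, right opposite
    z13 = np.array([rt, re_, la, rev, lev])  # right transitive, left opposite
    z24 = np.array([rt, re_, rev])  # left damaged -> right is transitive
    z34 = np.array([lt, le, lev])  # right damaged -> left is transitive
    return z12, z13, z24, z34


def transition_rates(
    baselines: BaselineIntensities, effects: CovariateEffects, visit: LocationVisit
) -> np.ndarray:
    """(a12, a13, a24, a34): intensities at frailty u = 1 for this visit's covariates."""
    z12, z13, z24, z34 = _activity_design(visit)
    b_nd, b_od = effects.as_arrays()
    lam = baselines.as_array()
    return np.array(
        [
            lam[0] * math.exp(float(z12 @ b_nd)),
            lam[1] * math.exp(float(z13 @ b_nd)),
            lam[2] * math.exp(float(z24 @ b_od)),
            lam[3] * math.exp(float(z34 @ b_od)),
        ]
    )


def build_intensity_matrix(
    baselines: BaselineIntensities,
    effects: CovariateEffects,
    visit: LocationVisit,
    u: float,
) -> np.ndarray:
    """4x4 generator with off-diagonal (i,j) = u * lambda0_ij * exp(beta' z)."""
    if not (u >= 0.0 and math.isfinite(u)):
        raise ValueError(f"frailty u must be finite and >= 0, got {u}")
    a12, a13, a24, a34 = u * transition_rates(baselines, effects, visit)
    Q = np.zeros((4, 4))
    Q[0, 1], Q[0, 2] = a12, a13
    Q[1, 3], Q[2, 3] = a24, a34
    Q[np.diag_indices(4)] = -Q.sum(axis=1)
    return Q


_NEAR_EQUAL = 1e-9


def interval_transition_matrix(Q: np.ndarray, dt: float) -> np.ndarray:
    """Transition probabilities over an interval of length dt under constant Q.

    Uses the acyclic closed form (exponential survival plus a one-step
    convolution on the 1->2->4 and 1->3->4 paths); falls back to the
    matrix exponential when the competing exit rates are near-equal and
    the convolution formula would divide by a vanishing rate difference.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (4, 4):
        raise ValueError("Q must be 4x4")
    offdiag = Q[~np.eye(4, dtype=bool)]
    if np.any(offdiag < -1e-12) or np.any(np.abs(Q.sum(axis=1)) > 1e-9):
        raise ValueError("Q must have nonnegative off-diagonals and zero row sums")
    if not (dt >= 0.0 and math.isfinite(dt)):
        raise ValueError(f"dt must be finite and >= 0, got {dt}")
    a12, a13, a24, a34 = Q[0, 1], Q[0, 2], Q[1, 3], Q[2, 3]
    r1 = a12 + a13
    scale = max(r1, a24, a34, 1.0)
    if (abs(r1 - a24) < _NEAR_EQUAL * scale and a12 > 0) or (
        abs(r1 - a34) < _NEAR_EQUAL * scale and a13 > 0
    ):
        return expm(Q * dt)
    P = np.zeros((4, 4))
    e1 = math.exp(-r1 * dt)
    e2 = math.exp(-a24 * dt)
    e3 = math.exp(-a34 * dt)
    P[0, 0] = e1
    P[0, 1] = a12 * (e2 - e1) / (r1 - a24) if a12 > 0 else 0.0
    P[0, 2] = a13 * (e3 - e1) / (r1 - a34) if a13 > 0 else 0.0
    P[0, 3] = max(0.0, 1.0 - P[0, 0] - P[0, 1] - P[0, 2])
    P[1, 1], P[1, 3] = e2, 1.0 - e2
    P[2, 2], P[2, 3] = e3, 1.0 - e3
    P[3, 3] = 1.0
    return P


def _check_location_visits(visits) -> None:
    if len(visits) == 0:
        raise ValueError("a location needs at least one visit")
    times = [v.time for v in visits]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("visit times must be strictly increasing within a location")
    for v1, v2 in zip(visits, visits[1:]):
        if (v1.state, v2.state) not in VALID_OBSERVED_PAIRS:
            raise ValueError(
                f"observed transition {v1.state}->{v2.state} violates the "
                "irreversible damage structure"
            )
        if (v1.left_ever_active and not v2.left_ever_active) or (
            v1.right_ever_active and not v2.right_ever_active
        ):
            raise ValueError("ever-active flags must be nondecreasing over visits")


def location_conditional_loglik(
    visits,
    baselines: BaselineIntensities,
    effects: CovariateEffects,
    u: float,
) -> float:
    """Panel log-likelihood of one location's visit sequence given frailty u.

    Sums log P(state_{j+1} | state_j) over consecutive visit pairs, with
    covariates frozen at their interval-start values.  A transition that
    is impossible given u (e.g. any damage when u = 0) yields -inf.
    """
    visits = list(visits)
    if len(visits) < 2:
        raise ValueError("location_conditional_loglik needs >= 2 visits")
    _check_location_visits(visits)
    total = 0.0
    for v1, v2 in zip(visits, visits[1:]):
        Q = build_intensity_matrix(baselines, effects, v1, u)
        P = interval_transition_matrix(Q, v2.time - v1.time)
        p = P[v1.state - 1, v2.state - 1]
        if p <= 0.0:
            logger.debug(
                "impossible transition %d->%d over dt=%.3f at u=%g",
                v1.state,
                v2.state,
                v2.time - v1.time,
                u,
            )
            return -math.inf
        total += math.log(p)
    return total


@dataclass
class PatientPanel:
    """One patient's clustered panel observations across joint locations.

    ``locations`` maps a location id (1-14) to the ordered visit list of
    that location.  Every location starts in state 1 at its first visit
    (the cohort entry criterion); locations with fewer than two visits
    carry no transition information.
    """

    patient_id: str
    locations: dict = field(default_factory=dict)
    baseline_covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for loc, visits in self.locations.items():
            visits = list(visits)
            _check_location_visits(visits)
            if visits[0].state != 1:
                raise ValueError(
                    f"patient {self.patient_id} location {loc}: first observed state "
                    f"must be 1 (no damage at entry), got {visits[0].state}"
                )
            self.locations[loc] = visits

    @property
    def is_observed_stayer(self) -> bool:
        """True when every observed state at every location is 1."""
        return all(v.state == 1 for visits in self.locations.values() for v in visits)

    @property
    def n_informative_locations(self) -> int:
        return sum(1 for visits in self.locations.values() if len(visits) >= 2)

    def informative_intervals(self):
        """Yield (visit_start, visit_end) pairs across all locations."""
        for visits in self.locations.values():
            yield from zip(visits, visits[1:])


def patient_conditional_lik(
    panel: PatientPanel,
    baselines: BaselineIntensities,
    effects: CovariateEffects,
    u: float,
) -> float:
    """Likelihood of one patient's panel given frailty u.

    Locations are conditionally independent given u, so this is the
    product over locations of the per-location likelihood; locations
    with a single visit contribute a factor of 1.
    """
    total = 0.0
    for visits in panel.locations.values():
        if len(visits) < 2:
            continue
        ll = location_conditional_loglik(visits, baselines, effects, u)
        if ll == -math.inf:
            return 0.0
        total += ll
    return math.exp(total)


# ---------------------------------------------------------------------------
# Vectorised panel kernel used by the marginal likelihood
# ---------------------------------------------------------------------------


@dataclass
class IntervalData:
    """All observation intervals of a cohort flattened into arrays.

    Design matrices hold the covariate vectors at interval start; rates
    are recomputed from them at each parameter value.  ``patient_index``
    maps every interval to its patient slot for segment sums.
    """

    from_state: np.ndarray
    to_state: np.ndarray
    dt: np.ndarray
    patient_index: np.ndarray
    Z12: np.ndarray
    Z13: np.ndarray
    Z24: np.ndarray
    Z34: np.ndarray
    n_patients: int
    patient_ids: list

    def __post_init__(self) -> None:
        # patient_index is contiguous nondecreasing by construction; reduceat
        # boundaries give cheap per-patient segment sums
        self._starts = np.searchsorted(self.patient_index, np.arange(self.n_patients))
        frm, to = self.from_state, self.to_state
        self._cases = {
            pair: np.flatnonzero((frm == pair[0]) & (to == pair[1]))
            for pair in ((1, 1), (1, 2), (1, 3), (1, 4), (2, 2), (2, 4), (3, 3), (3, 4))
        }

    @classmethod
    def from_panels(cls, panels) -> "IntervalData":
        frm, to, dt, pidx = [], [], [], []
        Z12, Z13, Z24, Z34 = [], [], [], []
        ids = []
        for k, panel in enumerate(panels):
            ids.append(panel.patient_id)
            for v1, v2 in panel.informative_intervals():
                z12, z13, z24, z34 = _activity_design(v1)
                frm.append(v1.state)
                to.append(v2.state)
                dt.append(v2.time - v1.time)
                pidx.append(k)
                Z12.append(z12)
                Z13.append(z13)
                Z24.append(z24)
                Z34.append(z34)
        if not frm:
            raise ValueError("cohort contains no informative intervals")
        return cls(
            from_state=np.array(frm, dtype=np.int8),
            to_state=np.array(to, dtype=np.int8),
            dt=np.array(dt),
            patient_index=np.array(pidx, dtype=np.int64),
            Z12=np.array(Z12),
            Z13=np.array(Z13),
            Z24=np.array(Z24),
            Z34=np.array(Z34),
            n_patients=len(ids),
            patient_ids=ids,
        )

    def rates(self, baselines: BaselineIntensities, effects: CovariateEffects) -> np.ndarray:
        """(n_intervals, 4) array of u=1 intensities (a12, a13, a24, a34)."""
        b_nd, b_od = effects.as_arrays()
        lam = baselines.as_array()
        if not hasattr(self, "_Znd"):
            # cache stacked designs: one matmul per coefficient block
            self._Znd = np.concatenate([self.Z12, self.Z13], axis=0)
            self._Zod = np.concatenate([self.Z24, self.Z34], axis=0)
        n = len(self.dt)
        lin_nd = self._Znd @ b_nd
        lin_od = self._Zod @ b_od
        out = np.empty((n, 4))
        out[:, 0] = lam[0] * np.exp(lin_nd[:n])
        out[:, 1] = lam[1] * np.exp(lin_nd[n:])
        out[:, 2] = lam[2] * np.exp(lin_od[:n])
        out[:, 3] = lam[3] * np.exp(lin_od[n:])
        return out


def _phi(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x)) / x, continuous at 0; stable for small and large x."""
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = -np.expm1(-x[nz]) / x[nz]
    return out


def conditional_loglik_by_patient(
    data: IntervalData,
    baselines: BaselineIntensities,
    effects: CovariateEffects,
    u_nodes: np.ndarray,
) -> np.ndarray:
    """(n_patients, n_nodes) conditional panel log-likelihoods.

    Evaluates every interval's transition probability in closed form for
    all frailty nodes at once, then segment-sums the logs per patient.
    Impossible transitions (probability 0 at a node) give -inf.
    """
    u = np.atleast_1d(np.asarray(u_nodes, dtype=float))
    rates = data.rates(baselines, effects)
    a12, a13, a24, a34 = rates.T
    r1 = a12 + a13
    cases = data._cases

    with np.errstate(divide="ignore", invalid="ignore"):
        # Survival rows (the bulk of panel data) in one outer product:
        # log P(stay) = -exit_rate * u * dt, with exit rate 0 in state 4.
        exit_rate = np.where(
            data.from_state == 1, r1, np.where(data.from_state == 2, a24, a34)
        )
        exit_rate[data.from_state == 4] = 0.0
        logp = np.multiply.outer(-exit_rate * data.dt, u)
        # rows that observed a move get the closed-form probabilities
        # 1 -> 2 (latent survival of the new right-joint hazard a24):
        # P = a12 u dt e^{-u a24 dt} phi(u (r1 - a24) dt),  phi(x) = (1-e^-x)/x
        for i, a_first, a_then in (
            (cases[(1, 2)], a12, a24),
            (cases[(1, 3)], a13, a34),
        ):
            if i.size:
                udt = np.multiply.outer(data.dt[i], u)
                x = udt * (r1[i] - a_then[i])[:, None]
                logp[i] = np.log(
                    a_first[i, None] * udt * np.exp(-a_then[i, None] * udt) * _phi(x)
                )
        i = cases[(1, 4)]
        if i.size:
            udt = np.multiply.outer(data.dt[i], u)
            x2 = udt * (r1[i] - a24[i])[:, None]
            x3 = udt * (r1[i] - a34[i])[:, None]
            p11 = np.exp(-r1[i, None] * udt)
            p12 = a12[i, None] * udt * np.exp(-a24[i, None] * udt) * _phi(x2)
            p13 = a13[i, None] * udt * np.exp(-a34[i, None] * udt) * _phi(x3)
            logp[i] = np.log(np.clip(1.0 - p11 - p12 - p13, 0.0, 1.0))
        for i, a_then in ((cases[(2, 4)], a24), (cases[(3, 4)], a34)):
            if i.size:
                udt = np.multiply.outer(data.dt[i], u)
                logp[i] = np.log(-np.expm1(-a_then[i, None] * udt))

    return np.add.reduceat(logp, data._starts, axis=0)
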