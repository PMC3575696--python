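"""Long-format panel CSV ingestion, validation and covariate preparation.

Schema (one row per patient x joint location x clinic visit):

======================  =====================================================
column                  meaning
======================  =====================================================
patient_id              patient identifier
location_id             joint location, 1-14
visit_time              years since clinic entry, >= 0
state                   damage state 1-4 (1 = neither joint damaged)
left_activity           0 = none, 1 = tenderness only, 2 = effusion
right_activity          as above, right joint
left_ever_active        0/1, left joint active at any visit so far
right_ever_active       0/1, right joint active at any visit so far
<extra columns>         patient-level covariates (e.g. esr), may be missing
======================  =====================================================
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .multistate import VALID_OBSERVED_PAIRS, LocationVisit, PatientPanel

logger = logging.getLogger(__name__)

__all__ = ["SCHEMA_COLUMNS", "read_panel", "write_panel", "prepare_stayer_covariate"]

SCHEMA_COLUMNS = [
    "patient_id",
    "location_id",
    "visit_time",
    "state",
    "left_activity",
    "right_activity",
    "left_ever_active",
    "right_ever_active",
]


def write_panel(panels, path, covariate_columns: dict | None = None) -> pd.DataFrame:
    """Write a cohort to the long-format CSV; returns the frame written.

    ``covariate_columns`` maps a column name to a per-patient-id dict of
    visit-level values; patient-level baseline covariates stored on the
    panels are written as constant columns.
    """
    rows = []
    for panel in panels:
        for loc, visits in sorted(panel.locations.items()):
            for v in visits:
                row = {
                    "patient_id": panel.patient_id,
                    "location_id": loc,
                    "visit_time": v.time,
                    "state": v.state,
                    "left_activity": v.left_activity,
                    "right_activity": v.right_activity,
                    "left_ever_active": int(v.left_ever_active),
                    "right_ever_active": int(v.right_ever_active),
                }
                row.update(panel.baseline_covariates)
                rows.append(row)
    df = pd.DataFrame(rows)
    if covariate_columns:
        for name, mapping in covariate_columns.items():
            df[name] = df["patient_id"].map(mapping)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def _location_violations(sub: pd.DataFrame) -> list[dict]:
    """Row-numbered validation failures within one patient x location block."""
    out = []
    times = sub["visit_time"].to_numpy()
    states = sub["state"].to_numpy()
    rows = sub.index.to_numpy()
    if np.any(np.diff(times) <= 0):
        i = int(np.argmax(np.diff(times) <= 0)) + 1
        kind = "duplicate_time" if times[i] == times[i - 1] else "nonincreasing_time"
        out.append({"row": int(rows[i]), "kind": kind})
    if states[0] != 1:
        out.append({"row": int(rows[0]), "kind": "first_state_not_1"})
    for i in range(1, len(states)):
        if (int(states[i - 1]), int(states[i])) not in VALID_OBSERVED_PAIRS:
            out.append(
                {
                    "row": int(rows[i]),
                    "kind": "forbidden_transition",
                    "detail": f"{states[i - 1]}->{states[i]}",
                }
            )
    ever = sub[["left_ever_active", "right_ever_active"]].to_numpy()
    if np.any(np.diff(ever.astype(int), axis=0) < 0):
        i = int(np.argmax(np.any(np.diff(ever.astype(int), axis=0) < 0, axis=1))) + 1
        out.append({"row": int(rows[i]), "kind": "ever_active_decrease"})
    return out


def read_panel(source, strict: bool = True):
    """Read a long-format panel CSV (or DataFrame) into PatientPanels.

    Returns ``(panels, report)`` where ``report`` lists violations with
    the offending 0-based data row numbers.  In strict mode any
    violation raises; in lenient mode offending locations are dropped
    with a warning.  Extra columns are attached as patient-level
    baseline covariates using each patient's first non-missing value.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file is missing required columns: {missing}")
    extra = [c for c in df.columns if c not in SCHEMA_COLUMNS]
    df = df.reset_index(drop=True)

    violations: list[dict] = []
    panels = []
    for pid, pat in df.groupby("patient_id", sort=False):
        locations = {}
        for loc, sub in pat.groupby("location_id", sort=True):
            sub = sub.sort_values("visit_time", kind="stable")
            bad = _location_violations(sub)
            if bad:
                for b in bad:
                    b.update(patient_id=pid, location_id=int(loc))
                violations.extend(bad)
                if strict:
                    continue  # collect all violations before raising
                logger.warning(
                    "dropping patient %s location %s: %d validation failure(s)",
                    pid,
                    loc,
                    len(bad),
                )
                continue
            locations[int(loc)] = [
                LocationVisit(
                    time=float(r.visit_time),
                    state=int(r.state),
                    left_activity=int(r.left_activity),
                    right_activity=int(r.right_activity),
                    left_ever_active=bool(r.left_ever_active),
                    right_ever_active=bool(r.right_ever_active),
                )
                for r in sub.itertuples()
            ]
        covs = {}
        for name in extra:
            vals = pat[name].dropna()
            if len(vals):
                covs[name] = float(vals.iloc[0])
        if locations:
            panels.append(
                PatientPanel(patient_id=str(pid), locations=locations, baseline_covariates=covs)
            )
    report = {"n_rows": len(df), "n_patients": len(panels), "violations": violations}
    if strict and violations:
        raise ValueError(
            f"panel validation failed with {len(violations)} violation(s); "
            f"first: {violations[0]}"
        )
    return panels, report


def prepare_stayer_covariate(source, name: str = "esr"):
    """Baseline value, imputation and standardization of a patient-level covariate.

    The baseline value is the first visit's value; when missing it is
    imputed from the earliest subsequent visit with a recorded value.
    Patients with no value at any visit are dropped (their count is
    logged).  The retained values are standardized by the cohort mean
    and standard deviation.

    ``source`` is the long-format DataFrame (or CSV path).  Returns
    ``(values, log)``: a Series of standardized baseline values indexed
    by patient_id, and a dict with counts and the centring constants.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    if name not in df.columns:
        raise ValueError(f"covariate column {name!r} absent from the panel data")
    baseline = {}
    n_imputed = 0
    dropped = []
    for pid, pat in df.groupby("patient_id", sort=False):
        pat = pat.sort_values("visit_time", kind="stable")
        per_visit = pat.groupby("visit_time", sort=True)[name].first()
        avail = per_visit.dropna()
        if avail.empty:
            dropped.append(pid)
            continue
        if np.isnan(per_visit.iloc[0]):
            n_imputed += 1
        baseline[pid] = float(avail.iloc[0])
    if dropped:
        logger.warning(
            "%d patient(s) have no %r value at any visit and were dropped", len(dropped), name
        )
    values = pd.Series(baseline, name=name)
    sd = float(values.std(ddof=1))
    mean = float(values.mean())
    if not np.isfinite(sd) or sd == 0.0:
        raise ValueError(f"cannot standardize {name!r}: zero or undefined standard deviation")
    standardized = (values - mean) / sd
    log = {
        "covariate": name,
        "n_patients": len(values) + len(dropped),
        "n_retained": len(values),
        "n_dropped_no_value": len(dropped),
        "dropped_patient_ids": [str(p) for p in dropped],
        "n_imputed_from_later_visit": n_imputed,
        "mean": mean,
        "sd": sd,
    }
    return standardized, log
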