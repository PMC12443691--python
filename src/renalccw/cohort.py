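"""Eligibility screening, KDIGO creatinine staging, and missing-data handling.

Staging uses the creatinine criterion only: stage 1 at >= 1.5x baseline or an
absolute rise >= 0.3 mg/dL within 48 h, stage 2 at >= 2.0x, stage 3 at >= 3.0x
or an absolute creatinine >= 4.0 mg/dL.  Baseline creatinine is the subject's
first recorded value.  Staging never looks at RRT receipt, so treatment cannot
leak into the severity classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d

from .config import EligibilityCriteria
from .simulate import Cohort

__all__ = [
    "kdigo_stage",
    "kdigo_stage_matrix",
    "apply_eligibility",
    "locf_impute",
    "pmm_impute",
]

#: time-varying fields eligible for last-observation-carried-forward filling
TIME_VARYING = (
    "sofa", "heart_rate", "resp_rate", "sbp", "dbp", "mbp", "temperature",
    "spo2", "ph", "bicarbonate", "lactate", "hemoglobin", "urea_nitrogen",
    "creatinine",
)

RISE_WINDOW_HOURS = 48


def kdigo_stage_matrix(creatinine: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Stage a (n_subjects, n_hours) creatinine matrix against per-subject
    baseline values.  Vectorised core shared by the simulator and the scalar
    per-subject API."""
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline creatinine must be positive")
    if np.any(creatinine <= 0):
        raise ValueError("creatinine values must be positive")
    ratio = creatinine / baseline[:, None]
    # trailing 48 h minimum (window includes the current hour)
    trail_min = minimum_filter1d(
        creatinine, size=RISE_WINDOW_HOURS + 1, axis=1, mode="nearest",
        origin=RISE_WINDOW_HOURS // 2,
    )
    rise = creatinine - trail_min
    stage = np.zeros(creatinine.shape, dtype=int)
    stage[(ratio >= 1.5) | (rise >= 0.3)] = 1
    stage[ratio >= 2.0] = 2
    stage[(ratio >= 3.0) | (creatinine >= 4.0)] = 3
    return stage


def kdigo_stage(creatinine_series, baseline_creatinine: float) -> np.ndarray:
    """KDIGO creatinine stage (0-3) for one subject's hourly series."""
    series = np.asarray(creatinine_series, dtype=float)
    return kdigo_stage_matrix(series[None, :], np.array([baseline_creatinine]))[0]


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

_REASON_ORDER = (
    "prior_ckd",
    "not_full_code",
    "icu_stay_lt_min",
    "on_rrt_before_eligibility",
    "died_before_eligibility",
    "insufficient_pre_hospitalization",
    "aki_stage_below_min",
    "resp_rate_below_min",
    "no_hour_meeting_all_criteria",
)


def apply_eligibility(
    cohort: Cohort, criteria: EligibilityCriteria
) -> tuple[pd.DataFrame, pd.Series]:
    """Screen the cohort and return one row per eligible subject at the FIRST
    hour all criteria hold, plus an exclusion tally.

    The eligible frame carries ``time_zero_hour``, ``aki_stage_at_t0``, the
    covariate snapshot at time zero (panel variables), baseline fields, and the
    outcome offsets ``init_offset`` / ``death_offset`` in hours since time
    zero (NaN when absent).  Exclusion reasons are attributed hierarchically in
    a fixed order so the tally sums to ``n_subjects - n_eligible``.
    """
    base = cohort.baseline.set_index("subject_id", drop=False)
    required = ["ckd", "full_code", "icu_discharge_hour", "hospital_pre_hours"]
    for col in required:
        if col not in base.columns:
            raise KeyError(f"baseline column missing: {col!r}")
        if base[col].isna().any():
            raise ValueError(f"missing required baseline field after imputation: {col!r}")

    window = int(criteria.eligibility_window_hours)
    panel = cohort.panel
    if panel["hour"].max() is not None and len(panel) and panel.duplicated(
            ["subject_id", "hour"]).any():
        raise ValueError("duplicate (subject_id, hour) rows in panel")

    # wide matrices over hours 0..window for the per-hour criteria
    sub = panel[panel["hour"] <= window]
    ids = base["subject_id"].to_numpy()
    pos = pd.Series(np.arange(len(ids)), index=ids)

    def wide(col):
        w = np.full((len(ids), window + 1), np.nan)
        w[pos[sub["subject_id"]].to_numpy(), sub["hour"].to_numpy()] = sub[col].to_numpy()
        return w

    # stage from the full panel so the 48 h rise rule sees the history;
    # baseline creatinine = first recorded value per subject
    first_creat = panel.sort_values(["subject_id", "hour"]).groupby("subject_id")[
        "creatinine"].first()
    if (first_creat <= 0).any():
        raise ValueError("nonpositive baseline creatinine")
    stage_w = wide("kdigo_stage") if "kdigo_stage" in panel.columns else None
    if stage_w is None:
        raise KeyError("panel must carry a kdigo_stage column (see kdigo_stage())")
    resp_w = wide("resp_rate")

    hours = np.arange(window + 1)[None, :]
    alive = ~np.isnan(resp_w)  # a panel row exists => alive (and measured) at that hour
    death = base["death_hour"].to_numpy(dtype=float)
    init = base["rrt_init_hour"].to_numpy(dtype=float)
    death = np.where(np.isnan(death), np.inf, death)
    init = np.where(np.isnan(init), np.inf, init)

    ok = (
        alive
        & (stage_w >= criteria.min_aki_stage)
        & (resp_w > criteria.min_resp_rate)
        & ((base["hospital_pre_hours"].to_numpy()[:, None] + hours)
           >= criteria.min_pre_randomization_hours)
        & (hours < base["icu_discharge_hour"].to_numpy()[:, None])
        & (hours < init[:, None])          # still RRT-naive at time zero
        & (hours < death[:, None])
    )
    subject_ok = base["icu_discharge_hour"].to_numpy() >= criteria.min_icu_hours
    if criteria.require_no_ckd:
        subject_ok = subject_ok & (base["ckd"].to_numpy() == 0)
    if criteria.require_full_code:
        subject_ok = subject_ok & (base["full_code"].to_numpy() == 1)
    ok &= subject_ok[:, None]

    any_ok = ok.any(axis=1)
    t0 = np.where(any_ok, np.argmax(ok, axis=1), -1)

    # --- exclusion tally (hierarchical attribution) --------------------------
    tally = {r: 0 for r in _REASON_ORDER}
    excl = ~any_ok
    remaining = excl.copy()

    def attribute(reason, mask):
        hit = remaining & mask
        tally[reason] += int(hit.sum())
        remaining[hit] = False

    attribute("prior_ckd", criteria.require_no_ckd & (base["ckd"].to_numpy() == 1))
    attribute("not_full_code",
              criteria.require_full_code & (base["full_code"].to_numpy() == 0))
    attribute("icu_stay_lt_min",
              base["icu_discharge_hour"].to_numpy() < criteria.min_icu_hours)
    attribute("on_rrt_before_eligibility", init == 0)
    attribute("died_before_eligibility", death <= 1)
    attribute("insufficient_pre_hospitalization",
              base["hospital_pre_hours"].to_numpy() + window
              < criteria.min_pre_randomization_hours)
    attribute("aki_stage_below_min",
              np.nan_to_num(stage_w, nan=-1.0).max(axis=1) < criteria.min_aki_stage)
    attribute("resp_rate_below_min",
              np.nan_to_num(resp_w, nan=-1.0).max(axis=1) <= criteria.min_resp_rate)
    attribute("no_hour_meeting_all_criteria", np.ones(len(ids), dtype=bool))
    tally_s = pd.Series(tally, name="n_excluded")

    idx = np.flatnonzero(any_ok)
    t0_el = t0[idx]
    snapshot = {}
    snap_pos = pos[ids[idx]].to_numpy()
    for col in TIME_VARYING + ("kdigo_stage",):
        w = wide(col)
        snapshot[col] = w[snap_pos, t0_el]

    eligible = pd.DataFrame({
        "subject_id": ids[idx],
        "time_zero_hour": t0_el.astype(float),
        "aki_stage_at_t0": snapshot["kdigo_stage"].astype(int),
        **{c: snapshot[c] for c in TIME_VARYING},
    })
    for col in ("age", "female", "race", "cci", "sepsis", "mech_vent",
                "vasopressor", "hospital_pre_hours", "icu_discharge_hour"):
        eligible[col] = base[col].to_numpy()[idx]
    eligible["init_offset"] = np.where(
        np.isfinite(init[idx]), init[idx] - t0_el, np.nan)
    eligible["death_offset"] = np.where(
        np.isfinite(death[idx]), death[idx] - t0_el, np.nan)
    return eligible.reset_index(drop=True), tally_s


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def locf_impute(panel: pd.DataFrame, columns=TIME_VARYING) -> pd.DataFrame:
    """Replace missing time-varying values with the subject's most recent
    observed value (previous-hour carry-forward).  A gap at the start of a
    subject's record, where no preceding hour exists, is filled from the first
    observed value of that variable — the recorded baseline measurement."""
    out = panel.sort_values(["subject_id", "hour"]).reset_index(drop=True)
    cols = [c for c in columns if c in out.columns]
    grouped = out.groupby("subject_id", sort=False)[cols]
    out[cols] = grouped.ffill()
    out[cols] = out.groupby("subject_id", sort=False)[cols].bfill()
    return out


def pmm_impute(
    baseline: pd.DataFrame,
    m: int = 1,
    k: int = 5,
    sweeps: int = 10,
    seed: int = 0,
    variables: tuple[str, ...] | None = None,
) -> list[pd.DataFrame]:
    """Chained-equations imputation with predictive mean matching.

    Each incomplete numeric variable is regressed (OLS) on the other model
    variables; every missing entry is replaced by the observed value of one of
    the ``k`` donors with nearest predicted mean.  Rows missing ``female``
    (sex) are dropped beforehand rather than imputed.  Returns ``m`` completed
    tables; imputed values always lie in the observed support.
    """
    rng = np.random.default_rng(seed)
    df = baseline.copy()
    if "female" in df.columns and df["female"].isna().any():
        df = df[df["female"].notna()].reset_index(drop=True)

    candidates = variables or ("age", "female", "cci", "sepsis", "mech_vent",
                               "vasopressor", "hospital_pre_hours")
    model_vars = [v for v in candidates if v in df.columns]
    incomplete = [v for v in model_vars if df[v].isna().any()]
    for v in incomplete:
        if df[v].notna().sum() == 0:
            raise ValueError(f"variable {v!r} has zero complete donors")
    if not incomplete:
        return [df.copy() for _ in range(m)]

    results = []
    X_all = df[model_vars].astype(float)
    for _ in range(m):
        work = X_all.copy()
        # initialise missing entries with the observed mean
        for v in incomplete:
            work[v] = work[v].fillna(X_all[v].mean())
        for _sweep in range(sweeps):
            for v in incomplete:
                obs = X_all[v].notna().to_numpy()
                others = [c for c in model_vars if c != v]
                A = np.column_stack([np.ones(len(work)), work[others].to_numpy()])
                y = X_all[v].to_numpy()
                beta, *_ = np.linalg.lstsq(A[obs], y[obs], rcond=None)
                pred = A @ beta
                donors_pred = pred[obs]
                donors_y = y[obs]
                for i in np.flatnonzero(~obs):
                    d = np.abs(donors_pred - pred[i])
                    pool = np.argpartition(d, min(k, len(d)) - 1)[:k]
                    work.iloc[i, work.columns.get_loc(v)] = donors_y[rng.choice(pool)]
        filled = df.copy()
        for v in incomplete:
            filled[v] = work[v].to_numpy()
            if pd.api.types.is_integer_dtype(baseline[v].dtype):
                filled[v] = filled[v].round().astype(baseline[v].dtype)
        results.append(filled)
    return results
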