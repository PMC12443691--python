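"""Clone each eligible subject into two strategy arms and censor deviations.

Each eligible subject is duplicated at time zero into an "early" clone
(initiate RRT within the grace period) and a "never" clone (never initiate).
Hourly checkpoints censor a clone the moment it deviates from its strategy:
the never clone at the hour RRT actually begins (any hour), the early clone at
the end of the grace period if RRT has not begun by then.  Deaths during the
grace period are events in every clone still uncensored, and a death falling
exactly on a censoring hour counts as an event (event takes precedence at
ties), so no grace-period death is lost.

All times are hours since time zero.  ``exit_offset`` is the end of the
clone's at-risk interval under the given horizon; exactly one of
``event``/``artificial_censor``/``admin_censor`` explains it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ARMS = ("early", "never")

__all__ = ["ARMS", "clone_subjects", "apply_protocol_censoring", "person_time_expand"]


def clone_subjects(eligible: pd.DataFrame, grace_hours: int) -> pd.DataFrame:
    """Duplicate each eligible subject into the two strategy arms.

    Returns one row per clone with identical subject data (``init_offset``,
    ``death_offset`` in hours since time zero) and an ``arm`` label; censoring
    is applied separately so that the pre-censoring representation keeps every
    factual death in both clones.
    """
    if (eligible["init_offset"] <= 0).any():
        raise ValueError("RRT initiation at or before time zero among eligible subjects")
    clones = pd.concat(
        [eligible.assign(arm=a) for a in ARMS], ignore_index=True
    ).sort_values(["subject_id", "arm"], ignore_index=True)
    clones["grace_hours"] = float(grace_hours)
    return clones


def apply_protocol_censoring(
    clones: pd.DataFrame, grace_hours: int, horizon_days: int = 90
) -> pd.DataFrame:
    """Resolve each clone's follow-up under hourly protocol checkpoints.

    Adds ``censor_offset`` (the artificial-censoring hour, NaN if none),
    ``exit_offset``, ``event``, ``artificial_censor`` and ``admin_censor``
    columns.  The never clone is censored at the initiation hour whenever RRT
    begins; the early clone is censored at ``grace_hours`` if RRT has not
    begun by then; adherent clones run to death or the administrative horizon.
    """
    out = clones.copy()
    init = out["init_offset"].to_numpy(dtype=float)
    death = out["death_offset"].to_numpy(dtype=float)
    init = np.where(np.isnan(init), np.inf, init)
    death = np.where(np.isnan(death), np.inf, death)
    if (init <= 0).any():
        raise ValueError("RRT initiation hour before time zero")
    horizon = float(horizon_days) * 24.0
    early = (out["arm"] == "early").to_numpy()

    censor = np.where(
        early,
        np.where(init <= grace_hours, np.inf, float(grace_hours)),
        init,
    )
    exit_ = np.minimum.reduce([death, censor, np.full_like(death, horizon)])
    event = death <= np.minimum(censor, horizon)          # ties go to the event
    artificial = ~event & (censor <= horizon)
    admin = ~event & ~artificial

    out["censor_offset"] = np.where(np.isfinite(censor), censor, np.nan)
    out["exit_offset"] = exit_
    out["event"] = event.astype(int)
    out["artificial_censor"] = artificial.astype(int)
    out["admin_censor"] = admin.astype(int)
    out["treated"] = ((init <= grace_hours) & early).astype(int)
    return out


def person_time_expand(
    clones: pd.DataFrame, grace_hours: int, panel: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Expand censored clones into discrete person-time.

    One row per clone-hour through the grace period and one row per clone-day
    afterwards; each row covers the interval ``(start, stop]`` and carries the
    at-risk/event/censor flags of the clone's last interval on its final row.
    With ``panel`` supplied, the time-varying covariates at the start of each
    interval are merged onto the rows (absolute hour = time zero + start).
    Deterministic ordering (subject_id, arm, stop).
    """
    req = {"exit_offset", "event", "artificial_censor", "admin_censor"}
    if not req <= set(clones.columns):
        raise KeyError("clones must be censored first (apply_protocol_censoring)")

    frames = []
    exit_ = clones["exit_offset"].to_numpy(dtype=float)
    for i, row_exit in enumerate(exit_):
        hourly_end = min(row_exit, float(grace_hours))
        stops = list(np.arange(1.0, np.floor(hourly_end) + 1.0))
        if hourly_end > (stops[-1] if stops else 0.0):
            stops.append(hourly_end)
        t = float(grace_hours)
        while t < row_exit:
            t = min(t + 24.0, row_exit)
            stops.append(t)
        stops = np.asarray(stops)
        starts = np.concatenate([[0.0], stops[:-1]])
        frames.append(pd.DataFrame({
            "row": i, "start": starts, "hour": stops,
        }))
    if not frames:
        return pd.DataFrame(columns=["subject_id", "arm", "start", "hour", "at_risk",
                                     "event", "artificial_censor", "admin_censor",
                                     "treated"])
    long = pd.concat(frames, ignore_index=True)
    meta = clones.reset_index(drop=True)
    long = long.join(
        meta[["subject_id", "arm", "exit_offset", "event", "artificial_censor",
              "admin_censor", "init_offset"]],
        on="row",
    )
    last = long["hour"] >= long["exit_offset"]
    long["at_risk"] = 1
    long["event"] = (long["event"] == 1) & last
    long["artificial_censor"] = (long["artificial_censor"] == 1) & last
    long["admin_censor"] = (long["admin_censor"] == 1) & last
    init = long["init_offset"].fillna(np.inf)
    long["treated"] = ((long["arm"] == "early") & (init <= long["hour"])).astype(int)
    for c in ("event", "artificial_censor", "admin_censor"):
        long[c] = long[c].astype(int)
    long = long.drop(columns=["row", "exit_offset"])
    if panel is not None:
        t0 = clones.reset_index(drop=True)[["subject_id", "time_zero_hour"]] \
            .drop_duplicates("subject_id")
        long = long.merge(t0, on="subject_id", how="left")
        long["abs_hour"] = np.floor(long["time_zero_hour"] + long["start"])
        cov_cols = [c for c in panel.columns if c not in ("subject_id", "hour")]
        pan = panel.rename(columns={"hour": "abs_hour"})
        long = long.merge(pan[["subject_id", "abs_hour"] + cov_cols],
                          on=["subject_id", "abs_hour"], how="left")
        long = long.drop(columns=["abs_hour"])
    return long.sort_values(["subject_id", "arm", "hour"], ignore_index=True)
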