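"""Synthetic ICU cohort generator with known counterfactual ground truth.

Stands in for a credentialed EHR extract.  Subjects get baseline
characteristics, hourly severity/vital/lab paths (mean-reverting AR(1)
processes; creatinine follows a subject-specific AKI trajectory), a confounded
discrete-time RRT-initiation hazard (sicker patients start RRT earlier), and a
discrete-time death hazard (hourly through the first week, daily to the
horizon).  Because every stochastic input is materialised as per-subject,
per-step uniform draws, potential outcomes under "initiate at time zero" and
"never initiate" can be replayed on shared randomness, yielding exact
counterfactual 30/90-day risks for any eligibility cohort.

Clock conventions: hour 0 is ICU admission.  An initiation recorded at hour j
occurred during the interval (j-1, j]; the death hazard in that interval uses
the treatment status at its start.  Death recorded at hour j means death during
(j-1, j]; the panel stops at j-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import SimConfig, EligibilityCriteria

__all__ = [
    "Cohort",
    "GroundTruth",
    "simulate_cohort",
    "simulate_counterfactual_truth",
    "simulate_cohort_with_truth",
    "inject_missingness",
]

PANEL_VARS = (
    "sofa", "heart_rate", "resp_rate", "sbp", "dbp", "mbp", "temperature",
    "spo2", "ph", "bicarbonate", "lactate", "hemoglobin", "urea_nitrogen",
    "creatinine",
)

BASELINE_COLS = (
    "subject_id", "age", "female", "race", "cci", "sepsis", "mech_vent",
    "vasopressor", "ckd", "full_code", "hospital_pre_hours",
    "icu_discharge_hour", "rrt_init_hour", "death_hour",
)


@dataclass
class Cohort:
    """Long-format cohort: one baseline row per subject, one panel row per
    subject-hour (columns ``subject_id``, ``hour``, vitals/labs, ``kdigo_stage``)."""

    baseline: pd.DataFrame
    panel: pd.DataFrame
    config: SimConfig | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.baseline)


@dataclass
class GroundTruth:
    """Counterfactual mortality risks among the eligible cohort.

    ``risk_early`` is the risk under the initiate-within-grace strategy: RRT
    begins at the subject's natural initiation hour when that falls inside the
    grace window and at the close of the window otherwise (with a 1-hour grace
    this is initiation at the first eligible hour).  ``risk_never`` is the risk
    under never initiating.  Both are averages over the same subjects on
    shared random numbers, so ``true_rd = risk_early - risk_never`` is exactly
    zero under a null treatment effect.
    """

    risk_early_90d: float
    risk_never_90d: float
    risk_early_30d: float
    risk_never_30d: float
    n_eligible: int
    defined: bool = True

    @property
    def true_rd_90d(self) -> float:
        return self.risk_early_90d - self.risk_never_90d

    @property
    def true_rd_30d(self) -> float:
        return self.risk_early_30d - self.risk_never_30d

    def to_dict(self) -> dict:
        return {
            "risk_early_90d": self.risk_early_90d,
            "risk_never_90d": self.risk_never_90d,
            "risk_early_30d": self.risk_early_30d,
            "risk_never_30d": self.risk_never_30d,
            "true_rd_90d": self.true_rd_90d,
            "true_rd_30d": self.true_rd_30d,
            "n_eligible": self.n_eligible,
            "defined": self.defined,
        }


# ---------------------------------------------------------------------------
# path simulation
# ---------------------------------------------------------------------------

# (stationary sd of hourly wiggle, hourly autocorrelation)
_AR_PARAMS = {
    "sofa": (None, 0.995),          # innovation handled separately (slow score)
    "heart_rate": (4.0, 0.95),
    "resp_rate": (1.5, 0.92),
    "sbp": (6.0, 0.92),
    "dbp": (4.0, 0.92),
    "temperature": (0.15, 0.95),
    "spo2": (0.8, 0.90),
    "ph": (0.02, 0.95),
    "bicarbonate": (0.8, 0.97),
    "lactate_log": (0.10, 0.97),
    "hemoglobin": (0.20, 0.98),
    "urea_nitrogen": (2.0, 0.98),
}


def _ar1_matrix(rng, mu, sd_stat, phi, n_steps):
    """Mean-reverting AR(1) path per subject: (n, n_steps) including t=0."""
    n = mu.shape[0]
    sigma = sd_stat * np.sqrt(1.0 - phi ** 2)
    x = np.empty((n, n_steps))
    x[:, 0] = mu + sd_stat * rng.standard_normal(n)
    eps = rng.standard_normal((n, n_steps - 1)) * sigma
    for t in range(1, n_steps):
        x[:, t] = mu + phi * (x[:, t - 1] - mu) + eps[:, t - 1]
    return x


def _extend_daily(rng, hourly, mu, sd_stat, phi, n_days):
    """Continue an hourly AR(1) path with exact 24-hour aggregated steps."""
    phi_d = phi ** 24
    sigma_d = sd_stat * np.sqrt(1.0 - phi_d ** 2)
    n = hourly.shape[0]
    out = np.empty((n, n_days))
    prev = hourly[:, -1]
    eps = rng.standard_normal((n, n_days)) * sigma_d
    for d in range(n_days):
        prev = mu + phi_d * (prev - mu) + eps[:, d]
        out[:, d] = prev
    return out


@dataclass
class _Paths:
    """Everything stochastic, on shared random numbers."""

    config: SimConfig
    hourly: dict                       # var -> (n, T_h) arrays, t = 0..T_h-1
    daily: dict                        # var -> (n, n_days) extension arrays
    base: pd.DataFrame                 # baseline frame without outcome columns
    kdigo: np.ndarray                  # (n, T_h) int stages
    kdigo_peak: np.ndarray             # (n, T_h) running maximum stage
    u_die: np.ndarray                  # (n, S) uniforms for the death process
    init_candidate: np.ndarray         # (n,) candidate initiation hour (inf if none)
    p_trt: np.ndarray                  # (n, T_h) true hourly initiation probabilities
    step_start: np.ndarray             # (S,) interval start hours
    step_dt: np.ndarray                # (S,) interval lengths (h)
    lp_death_base: np.ndarray          # (n, S) death-hazard linear predictor, untreated

    def death_hours(self, init_hour: np.ndarray, effect: np.ndarray) -> np.ndarray:
        """First-passage death hour given per-subject initiation hour and
        log-HR effect; inf when no death before the end of simulated time."""
        treated = init_hour[:, None] <= self.step_start[None, :]
        p = expit(self.lp_death_base + effect[:, None] * treated)
        died = self.u_die < p
        first = np.argmax(died, axis=1)
        any_death = died.any(axis=1)
        end_times = self.step_start + self.step_dt
        out = np.where(any_death, end_times[first], np.inf)
        return out


def _simulate_paths(config: SimConfig) -> _Paths:
    n = config.n_subjects
    rng = np.random.default_rng(config.seed)
    T_h = config.hourly_hours

    # --- baseline characteristics -------------------------------------------
    age = np.clip(rng.normal(65.0, 15.0, n), 18.0, 95.0)
    female = (rng.random(n) < 0.40).astype(int)
    race = rng.choice(
        ["white", "black", "asian", "hispanic", "other"],
        size=n, p=[0.62, 0.15, 0.03, 0.05, 0.15],
    )
    cci = np.clip(np.round(rng.normal(7.0, 3.0, n)), 0, 20).astype(int)
    sepsis = (rng.random(n) < 0.62).astype(int)
    mech_vent = (rng.random(n) < 0.40).astype(int)
    ckd = (rng.random(n) < 0.08).astype(int)
    full_code = (rng.random(n) < 0.92).astype(int)
    hospital_pre_hours = np.round(rng.uniform(0.0, 48.0, n))
    icu_discharge_hour = np.maximum(
        12.0, np.round(np.exp(rng.normal(np.log(110.0), 0.55, n)))
    )

    # --- AKI trajectory: creatinine multiplier -------------------------------
    # ~25% of subjects have no acute kidney injury; the rest ramp creatinine
    # toward a subject-specific peak ratio m over ~30 h.
    no_aki = rng.random(n) < 0.25
    m = np.where(
        no_aki,
        np.exp(rng.normal(0.0, 0.08, n)),
        np.exp(rng.normal(np.log(2.0), 0.50, n)),
    )
    c0 = np.exp(rng.normal(np.log(1.05), 0.22, n))

    # severity anchor: renal injury and sepsis raise the SOFA set point
    sofa_mu = np.clip(
        rng.normal(6.0, 3.0, n) + 2.2 * np.log(np.maximum(m, 1.0))
        + 1.2 * sepsis + 1.0 * mech_vent,
        0.0, 24.0,
    )
    vasopressor = (rng.random(n) < expit(-3.6 + 0.08 * (sofa_mu - 7.0))).astype(int)

    # --- hourly paths --------------------------------------------------------
    hourly: dict[str, np.ndarray] = {}
    mus = {
        "heart_rate": rng.normal(87.0, 9.0, n),
        "resp_rate": rng.normal(20.0, 3.0, n),
        "sbp": rng.normal(113.0, 13.0, n),
        "dbp": rng.normal(60.0, 8.0, n),
        "temperature": rng.normal(36.87, 0.26, n),
        "spo2": rng.normal(97.3, 1.5, n),
        "ph": rng.normal(7.37, 0.055, n),
        "bicarbonate": rng.normal(22.4, 3.0, n),
        "lactate_log": rng.normal(np.log(1.9), 0.45, n),
        "hemoglobin": rng.normal(9.0, 1.0, n),
        "urea_nitrogen": np.maximum(5.0, rng.normal(39.0, 15.0, n)),
    }
    for var, (sd_stat, phi) in _AR_PARAMS.items():
        if var == "sofa":
            continue
        hourly[var] = _ar1_matrix(rng, mus[var], sd_stat, phi, T_h)

    sofa = _ar1_matrix(rng, sofa_mu, 1.6, _AR_PARAMS["sofa"][1], T_h)
    hourly["sofa"] = np.clip(sofa, 0.0, 24.0)
    hourly["spo2"] = np.minimum(hourly["spo2"], 100.0)
    hourly["resp_rate"] = np.maximum(hourly["resp_rate"], 4.0)
    hourly["lactate"] = np.exp(hourly.pop("lactate_log"))
    hourly["mbp"] = (hourly["sbp"] + 2.0 * hourly["dbp"]) / 3.0 \
        + rng.normal(0.0, 3.0, (n, T_h))

    t_grid = np.arange(T_h)[None, :]
    ramp = 1.0 + (m[:, None] - 1.0) * (1.0 - np.exp(-t_grid / 30.0))
    creat_noise = _ar1_matrix(rng, np.zeros(n), 0.04, 0.95, T_h)
    hourly["creatinine"] = np.maximum(c0[:, None] * ramp * np.exp(creat_noise), 0.2)

    from .cohort import kdigo_stage_matrix  # staging shared with the cohort module
    kdigo = kdigo_stage_matrix(hourly["creatinine"], c0)
    kdigo_peak = np.maximum.accumulate(kdigo, axis=1)

    # --- daily extensions for the death-hazard covariates --------------------
    max_hour = 72 + config.horizon_hours  # latest time zero + horizon
    n_days = max(0, int(np.ceil((max_hour - T_h) / 24.0)))
    daily = {
        "sofa": np.clip(
            _extend_daily(rng, hourly["sofa"], sofa_mu, 1.6, _AR_PARAMS["sofa"][1], n_days),
            0.0, 24.0,
        ),
        "lactate": np.exp(
            _extend_daily(rng, np.log(np.maximum(hourly["lactate"], 1e-3)),
                          mus["lactate_log"], 0.10, 0.97, n_days)
        ),
    }

    # --- treatment (RRT initiation) process, hours 1..T_h --------------------
    lp_trt = np.full((n, T_h), config.treatment_intercept)
    covs = {"age": age[:, None], "sepsis": sepsis[:, None], "female": female[:, None],
            "cci": cci[:, None]}
    for name, coef in config.baseline_coefs.items():
        x = hourly[name][:, :T_h] if name in hourly else covs[name]
        lp_trt = lp_trt + coef * x
    lp_trt = lp_trt - t_grid / config.treatment_time_decay_hours
    p_trt = expit(lp_trt)
    u_trt = rng.random((n, T_h))
    hit = u_trt < p_trt  # initiation during (j-1, j] decided on covariates at j-1
    first = np.argmax(hit, axis=1)
    init_candidate = np.where(hit.any(axis=1), first + 1.0, np.inf)

    # --- death process: hourly steps 1..T_h, daily steps afterwards ----------
    step_start = np.concatenate([
        np.arange(T_h, dtype=float),                       # hourly intervals
        T_h + 24.0 * np.arange(n_days, dtype=float),       # daily intervals
    ])
    step_dt = np.concatenate([np.ones(T_h), np.full(n_days, 24.0)])
    S = step_start.size

    lp = np.full((n, S), config.outcome_intercept) + np.log(step_dt)[None, :] \
        - (step_start[None, :] / config.outcome_time_decay_hours)
    for name, coef in config.outcome_coefs.items():
        if name in hourly:
            x = np.concatenate([hourly[name], daily[name]], axis=1) if name in daily \
                else np.concatenate(
                    [hourly[name], np.repeat(hourly[name][:, -1:], n_days, axis=1)], axis=1)
        else:
            x = np.repeat(covs[name], S, axis=1)
        lp = lp + coef * x
    u_die = rng.random((n, S))

    base = pd.DataFrame({
        "subject_id": np.arange(n),
        "age": age, "female": female, "race": race, "cci": cci,
        "sepsis": sepsis, "mech_vent": mech_vent, "vasopressor": vasopressor,
        "ckd": ckd, "full_code": full_code,
        "hospital_pre_hours": hospital_pre_hours,
        "icu_discharge_hour": icu_discharge_hour,
    })

    return _Paths(
        config=config, hourly=hourly, daily=daily, base=base, kdigo=kdigo,
        kdigo_peak=kdigo_peak,
        u_die=u_die, init_candidate=init_candidate, p_trt=p_trt,
        step_start=step_start, step_dt=step_dt, lp_death_base=lp,
    )


def _stage_at(paths: _Paths, hour: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Peak KDIGO stage reached by a given (integer) hour, for the subjects
    in ``rows`` (matrix row indices aligned with ``hour``).

    Stage-dependent treatment effects key on the severity the kidney injury
    has attained, so a transient dip below a threshold does not reclassify a
    subject between counterfactual arms.
    """
    idx = np.clip(hour, 0, paths.kdigo_peak.shape[1] - 1).astype(int)
    return paths.kdigo_peak[np.asarray(rows, dtype=int), idx]


def _factual_outcomes(paths: _Paths) -> tuple[np.ndarray, np.ndarray]:
    """(rrt_init_hour, death_hour) under the factual treatment process."""
    cfg = paths.config
    effect_map = cfg.effect_by_stage()
    init_c = paths.init_candidate
    finite = np.isfinite(init_c)
    stage_at_init = np.zeros(len(init_c), dtype=int)
    stage_at_init[finite] = _stage_at(
        paths, init_c[finite], np.flatnonzero(finite))
    effect = np.array([effect_map[s] for s in stage_at_init], dtype=float)
    effect = np.where(finite, effect, 0.0)

    death = paths.death_hours(init_c, effect)
    init = np.where(death > init_c, init_c, np.inf)  # death first => never initiated
    return init, death


def _build_cohort(paths: _Paths, init: np.ndarray, death: np.ndarray) -> Cohort:
    cfg = paths.config
    n = cfg.n_subjects
    base = paths.base.copy()
    base["rrt_init_hour"] = np.where(np.isfinite(init), init, np.nan)
    base["death_hour"] = np.where(np.isfinite(death), death, np.nan)

    T_h = cfg.hourly_hours
    # panel rows 0 .. min(T_h - 1, death_hour - 1)
    last = np.minimum(T_h - 1, np.where(np.isfinite(death), death - 1, T_h - 1)).astype(int)
    counts = last + 1
    sid = np.repeat(np.arange(n), counts)
    hour = np.concatenate([np.arange(c) for c in counts]) if n else np.array([], dtype=int)
    cols = {"subject_id": sid, "hour": hour}
    for var in PANEL_VARS:
        cols[var] = paths.hourly[var][sid, hour]
    cols["kdigo_stage"] = paths.kdigo[sid, hour]
    panel = pd.DataFrame(cols)
    panel["sofa"] = panel["sofa"].round(1)
    return Cohort(baseline=base, panel=panel, config=cfg)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a complete (no missingness) synthetic cohort.

    Deterministic given the config: identical config (including seed) yields
    byte-identical tables.
    """
    paths = _simulate_paths(config)
    init, death = _factual_outcomes(paths)
    return _build_cohort(paths, init, death)


def _truth_from_paths(
    paths: _Paths, t0: np.ndarray, subject_ids: np.ndarray
) -> GroundTruth:
    """Counterfactual risks for the given eligible subjects/time zeros.

    The early strategy initiates at the subject's natural initiation hour when
    it falls within the grace window and at the close of the window otherwise;
    the never strategy never initiates.  Shared uniforms make the two paths
    (and the factual path) agree wherever treatment has no effect.
    """
    cfg = paths.config
    if len(subject_ids) == 0:
        return GroundTruth(np.nan, np.nan, np.nan, np.nan, 0, defined=False)
    effect_map = cfg.effect_by_stage()
    n_all = cfg.n_subjects

    t0_full = np.full(n_all, np.inf)
    t0_full[subject_ids] = t0
    init_early = np.minimum(paths.init_candidate, t0_full + cfg.grace_hours)
    stage_init = np.zeros(n_all, dtype=int)
    stage_init[subject_ids] = _stage_at(paths, init_early[subject_ids], subject_ids)
    effect = np.array([effect_map[s] for s in stage_init], dtype=float)

    death_early = paths.death_hours(init_early, effect)[subject_ids]
    death_never = paths.death_hours(np.full(n_all, np.inf), np.zeros(n_all))[subject_ids]

    def risk(death_arr, days):
        return float(np.mean(death_arr <= t0 + days * 24.0))

    return GroundTruth(
        risk_early_90d=risk(death_early, 90),
        risk_never_90d=risk(death_never, 90),
        risk_early_30d=risk(death_early, 30),
        risk_never_30d=risk(death_never, 30),
        n_eligible=len(subject_ids),
    )


def simulate_counterfactual_truth(
    config: SimConfig, criteria: EligibilityCriteria | None = None
) -> GroundTruth:
    """Replay both potential outcome paths (initiate within the grace window
    vs. never initiate) on shared random numbers and return counterfactual
    risks among the eligibility cohort defined by ``criteria`` (default:
    broad stage >= 1)."""
    _, truth = simulate_cohort_with_truth(config, criteria)
    return truth


def simulate_cohort_with_truth(
    config: SimConfig, criteria: EligibilityCriteria | None = None
) -> tuple[Cohort, GroundTruth]:
    """One shared-randomness pass returning the factual cohort and its truth."""
    from .cohort import apply_eligibility

    criteria = criteria or EligibilityCriteria()
    paths = _simulate_paths(config)
    init, death = _factual_outcomes(paths)
    cohort = _build_cohort(paths, init, death)
    if config.n_subjects == 0:
        return cohort, GroundTruth(np.nan, np.nan, np.nan, np.nan, 0, defined=False)
    eligible, _ = apply_eligibility(cohort, criteria)
    truth = _truth_from_paths(
        paths,
        eligible["time_zero_hour"].to_numpy(dtype=float),
        eligible["subject_id"].to_numpy(),
    )
    return cohort, truth


def inject_missingness(
    cohort: Cohort, missing_rates: Mapping[str, float], seed: int = 0
) -> tuple[Cohort, dict[str, int]]:
    """Punch independent holes into baseline/panel fields at the stated rates.

    Returns the degraded cohort (copy) and a per-variable count of injected
    missing values.  A rate on ``female`` emulates missing sex, which the
    imputation stage removes rather than imputes.
    """
    for name, rate in missing_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missing rate for {name!r} outside [0, 1]: {rate}")
    rng = np.random.default_rng(seed)
    baseline = cohort.baseline.copy()
    panel = cohort.panel.copy()
    counts: dict[str, int] = {}
    for name, rate in missing_rates.items():
        if rate == 0.0:
            counts[name] = 0
            continue
        if name in panel.columns and name not in ("subject_id", "hour"):
            mask = rng.random(len(panel)) < rate
            panel.loc[mask, name] = np.nan
            counts[name] = int(mask.sum())
        elif name in baseline.columns:
            mask = rng.random(len(baseline)) < rate
            if baseline[name].dtype == object:
                baseline.loc[mask, name] = None
            else:
                baseline[name] = baseline[name].astype(float)
                baseline.loc[mask, name] = np.nan
            counts[name] = int(mask.sum())
        else:
            raise KeyError(f"unknown variable for missingness injection: {name!r}")
    return Cohort(baseline=baseline, panel=panel, config=cohort.config), counts
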