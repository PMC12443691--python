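"""Outcome models on the weighted clone data.

The primary contrast is the early-initiation arm's hazard ratio from a Cox
partial likelihood that incorporates the clone weights, with a sandwich
variance clustered on subjects (each subject contributes two correlated
clones).  Follow-up is measured in days from time zero.  Weight updates inside
the 72-hour grace window enter the Cox risk sets as counting-process episodes
split at day boundaries; after grace the frozen weight carries one long
episode to the event or horizon.

A Weibull accelerated-failure-time model serves as the sensitivity analysis
free of the proportional-hazards assumption; its exponentiated arm coefficient
is an acceleration factor (time ratio) and its clustered sandwich errors are
assembled from per-row numerical scores at the MLE.  Under a Weibull
proportional-hazards law with shape k the two parameterizations are linked by
HR = AF^(-k), which the test suite exploits as a self-consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter, WeibullAFTFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from .config import OUTCOME_COVARIATES
from .weights import WeightedClones

__all__ = [
    "HazardEstimate",
    "PHTestResult",
    "AFTEstimate",
    "build_cox_intervals",
    "build_clone_frame",
    "fit_weighted_cox",
    "fit_naive_cox",
    "test_proportional_hazards",
    "fit_weibull_aft",
    "survival_curves",
]

#: default adjustment set of the outcome models: the weight-model baseline
#: covariates plus the additional prognostic labs/vitals, all at time zero
from .config import WEIGHT_DENOMINATOR_COVARIATES
DEFAULT_ADJUSTMENT = tuple(WEIGHT_DENOMINATOR_COVARIATES) + tuple(OUTCOME_COVARIATES)


@dataclass
class HazardEstimate:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    robust_se: float
    horizon_days: int
    n_events: int
    n_clones: int
    fitter: object = field(repr=False, default=None)
    training_frame: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"hr": self.hr, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "p_value": self.p_value, "robust_se": self.robust_se,
                "horizon_days": self.horizon_days, "n_events": self.n_events}


@dataclass
class PHTestResult:
    global_p: float
    global_stat: float
    per_covariate: pd.DataFrame

    def to_dict(self) -> dict:
        return {"global_p": self.global_p, "global_stat": self.global_stat}


@dataclass
class AFTEstimate:
    acceleration_factor: float
    ci_low: float
    ci_high: float
    p_value: float
    robust_se: float
    weibull_shape: float
    horizon_days: int
    fitter: object = field(repr=False, default=None)

    @property
    def percent_change(self) -> float:
        """Reporting convention: (1 - AF)*100 as a percent reduction in
        survival time when AF < 1, (AF - 1)*100 as percent longer when AF > 1."""
        if self.acceleration_factor >= 1.0:
            return (self.acceleration_factor - 1.0) * 100.0
        return (1.0 - self.acceleration_factor) * 100.0

    def describe(self) -> str:
        af = self.acceleration_factor
        if af >= 1.0:
            return f"{af:.2f} times longer survival time"
        return f"{self.percent_change:.1f}% reduction in survival time"

    def to_dict(self) -> dict:
        return {"acceleration_factor": self.acceleration_factor,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "p_value": self.p_value, "robust_se": self.robust_se,
                "weibull_shape": self.weibull_shape,
                "percent_change": self.percent_change,
                "description": self.describe(),
                "horizon_days": self.horizon_days}


# ---------------------------------------------------------------------------
# data layout builders
# ---------------------------------------------------------------------------

def _horizon_outcomes(clones: pd.DataFrame, horizon_days: int):
    """Exit (hours) and event status re-censored at the requested horizon."""
    H = horizon_days * 24.0
    exit_ = np.minimum(clones["exit_offset"].to_numpy(dtype=float), H)
    event = (clones["event"].to_numpy() == 1) & (
        clones["exit_offset"].to_numpy() <= H)
    return exit_, event


def _sw_wide(weighted: WeightedClones, grace_hours: int) -> dict[str, np.ndarray]:
    """Truncated weight per clone-hour as (subject x hour) matrices, frozen
    (forward-filled) past each clone's resolution."""
    pt = weighted.person_time
    subjects = weighted.clones["subject_id"].drop_duplicates().to_numpy()
    pos = pd.Series(np.arange(len(subjects)), index=subjects)
    out = {}
    for arm in ("early", "never"):
        sub = pt[pt["arm"] == arm]
        W = np.full((len(subjects), grace_hours), np.nan)
        W[pos[sub["subject_id"]].to_numpy(),
          sub["hour"].to_numpy().astype(int) - 1] = sub["sw_trunc"].to_numpy()
        W = pd.DataFrame(W).ffill(axis=1).fillna(1.0).to_numpy()
        out[arm] = W
    out["subjects"] = subjects
    return out


def build_cox_intervals(
    weighted: WeightedClones,
    grace_hours: int,
    horizon_days: int,
    covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT,
) -> pd.DataFrame:
    """Counting-process episodes for the weighted Cox fit.

    Each clone is split at day boundaries inside the grace window (where its
    weight is still evolving) and runs as one frozen-weight episode
    afterwards.  Times are days since time zero; covariates are the time-zero
    snapshot.
    """
    clones = weighted.clones
    W = _sw_wide(weighted, grace_hours)
    pos = pd.Series(np.arange(len(W["subjects"])), index=W["subjects"])

    bounds = np.arange(24.0, grace_hours + 1.0, 24.0)
    if not len(bounds) or bounds[-1] < grace_hours:
        bounds = np.append(bounds, float(grace_hours))

    exit_h, event = _horizon_outcomes(clones, horizon_days)
    k = np.searchsorted(bounds, exit_h, side="left")  # boundaries strictly before exit
    counts = k + 1
    ridx = np.repeat(np.arange(len(clones)), counts)
    stop_h = np.concatenate([
        np.append(bounds[:kk], e) for kk, e in zip(counts - 1, exit_h)
    ]) if len(clones) else np.array([])
    is_last = np.concatenate([
        np.append(np.zeros(kk, dtype=bool), True) for kk in (counts - 1)
    ]) if len(clones) else np.array([], dtype=bool)
    start_h = np.concatenate([
        np.concatenate([[0.0], np.append(bounds[:kk], e)[:-1]])
        for kk, e in zip(counts - 1, exit_h)
    ]) if len(clones) else np.array([])

    sid = clones["subject_id"].to_numpy()[ridx]
    arm = clones["arm"].to_numpy()[ridx]
    hr_idx = np.clip(np.ceil(stop_h).astype(int), 1, grace_hours) - 1
    w_early = W["early"][pos[sid].to_numpy(), hr_idx]
    w_never = W["never"][pos[sid].to_numpy(), hr_idx]
    weight = np.where(arm == "early", w_early, w_never)

    df = pd.DataFrame({
        "subject_id": sid,
        "arm": arm,
        "early": (arm == "early").astype(int),
        "entry": start_h / 24.0,
        "stop": stop_h / 24.0,
        "event": (event[ridx] & is_last).astype(int),
        "weight": weight,
    })
    for c in covariates:
        df[c] = clones[c].to_numpy()[ridx]
    df = df[df["stop"] > df["entry"]].reset_index(drop=True)
    return df


def build_clone_frame(
    weighted: WeightedClones,
    horizon_days: int,
    covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT,
) -> pd.DataFrame:
    """One row per clone with frozen truncated weight (AFT / KM layout)."""
    clones = weighted.clones
    exit_h, event = _horizon_outcomes(clones, horizon_days)
    df = pd.DataFrame({
        "subject_id": clones["subject_id"].to_numpy(),
        "arm": clones["arm"].to_numpy(),
        "early": (clones["arm"] == "early").astype(int).to_numpy(),
        "duration": np.maximum(exit_h / 24.0, 1e-6),
        "event": event.astype(int),
        "weight": clones["sw_trunc_final"].to_numpy(),
    })
    for c in covariates:
        df[c] = clones[c].to_numpy()
    return df


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def _check_outcome_frame(df: pd.DataFrame) -> None:
    if (df["weight"] <= 0).any():
        raise ValueError("nonpositive weights in outcome data")
    arm = df["arm"] if "arm" in df.columns else df["early"]
    events_by_arm = df.groupby(arm)["event"].sum()
    if (events_by_arm == 0).any():
        empty = events_by_arm[events_by_arm == 0].index.tolist()
        raise ValueError(f"no events in arm(s): {empty}")


def fit_weighted_cox(
    intervals: pd.DataFrame,
    horizon_days: int,
    covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT,
) -> HazardEstimate:
    """Arm hazard ratio from the weight-incorporating Cox partial likelihood.

    Efron handling of the many tied event times on the discrete grid; robust
    sandwich SE clustered on subject_id, since a subject's two clones are
    duplicated data, not independent observations.
    """
    _check_outcome_frame(intervals)
    cols = ["entry", "stop", "event", "weight", "subject_id", "early", *covariates]
    import warnings
    from lifelines.exceptions import ConvergenceError
    cph = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # tiny ridge, escalated only on convergence failure (near-collinear
        # covariates with few events can stall the Newton steps)
        for pen in (0.0, 1e-3, 1e-2, 1e-1):
            try:
                cph = CoxPHFitter(penalizer=pen)
                cph.fit(
                    intervals[cols],
                    duration_col="stop",
                    entry_col="entry",
                    event_col="event",
                    weights_col="weight",
                    cluster_col="subject_id",
                    robust=True,
                )
                break
            except (ConvergenceError, ValueError) as exc:
                last = exc
                cph = None
        if cph is None:
            raise RuntimeError(f"weighted Cox did not converge: {last}")
    coef = float(cph.params_["early"])
    se = float(cph.standard_errors_["early"])
    z = coef / se
    return HazardEstimate(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959964 * se)),
        ci_high=float(np.exp(coef + 1.959964 * se)),
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        robust_se=se,
        horizon_days=horizon_days,
        n_events=int(intervals["event"].sum()),
        n_clones=int(intervals.groupby(["subject_id", "early"]).ngroups),
        fitter=cph,
        training_frame=intervals[cols],
    )


def fit_naive_cox(
    eligible: pd.DataFrame,
    horizon_days: int,
    covariates: tuple[str, ...] = (),
) -> HazardEstimate:
    """Naive ever-vs-never-treated Cox on subjects (no cloning).

    Classifies each subject by whether RRT was ever initiated during
    follow-up — the comparison the clone-censor-weight design exists to
    avoid.  Unadjusted by default (the crude analysis), so the estimate
    carries both confounding by indication and immortal time bias; pass the
    time-zero covariates to isolate the immortal-time component.
    """
    H = horizon_days * 24.0
    death = eligible["death_offset"].to_numpy(dtype=float)
    death = np.where(np.isnan(death), np.inf, death)
    init = eligible["init_offset"].to_numpy(dtype=float)
    ever = np.isfinite(init) & (init <= H)
    df = pd.DataFrame({
        "duration": np.maximum(np.minimum(death, H) / 24.0, 1e-6),
        "event": (death <= H).astype(int),
        "early": ever.astype(int),
    })
    for c in covariates:
        df[c] = eligible[c].to_numpy()
    import warnings
    from lifelines.exceptions import ConvergenceError
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pen in (0.0, 1e-3, 1e-2, 1e-1):
            try:
                cph = CoxPHFitter(penalizer=pen)
                cph.fit(df, duration_col="duration", event_col="event")
                break
            except (ConvergenceError, ValueError):
                cph = None
        if cph is None:
            raise RuntimeError("naive Cox did not converge")
    coef = float(cph.params_["early"])
    se = float(cph.standard_errors_["early"])
    return HazardEstimate(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959964 * se)),
        ci_high=float(np.exp(coef + 1.959964 * se)),
        p_value=float(2.0 * stats.norm.sf(abs(coef / se))),
        robust_se=se,
        horizon_days=horizon_days,
        n_events=int(df["event"].sum()),
        n_clones=len(df),
        fitter=cph,
        training_frame=df,
    )


def test_proportional_hazards(estimate: HazardEstimate) -> PHTestResult:
    """Schoenfeld-residual test of proportional hazards.

    Per-covariate tests come from correlating scaled Schoenfeld residuals with
    Kaplan-Meier-transformed time; the global statistic sums the per-covariate
    chi-squares (df = number of covariates) — exact for a single covariate,
    an independence approximation otherwise.
    """
    if estimate.fitter is None or estimate.training_frame is None:
        raise ValueError("estimate must carry its fitted model")
    if estimate.n_events == 0:
        raise ValueError("no events: proportional-hazards test undefined")
    frame = estimate.training_frame
    fitter = estimate.fitter
    if getattr(fitter, "entry_col", None) is not None:
        # lifelines cannot form Schoenfeld residuals on left-truncated
        # episodes: collapse to one row per clone (frozen final weight) and
        # refit for the diagnostic
        agg = {"stop": "max", "event": "max", "weight": "last"}
        covs = [c for c in frame.columns
                if c not in ("entry", "stop", "event", "weight", "subject_id", "early")]
        agg.update({c: "last" for c in covs})
        frame = (frame.sort_values(["subject_id", "early", "stop"])
                 .groupby(["subject_id", "early"], sort=False).agg(agg).reset_index())
        import warnings
        fitter = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(frame.drop(columns=["subject_id"]), duration_col="stop",
                       event_col="event", weights_col="weight", robust=True)
        frame = frame.drop(columns=["subject_id"])
    res = proportional_hazard_test(fitter, frame, time_transform="km")
    per = res.summary.reset_index().rename(columns={"index": "covariate"})
    stat = float(per["test_statistic"].sum())
    df_ = len(per)
    return PHTestResult(
        global_p=float(stats.chi2.sf(stat, df_)),
        global_stat=stat,
        per_covariate=per,
    )


# ---------------------------------------------------------------------------
# Weibull AFT with clustered sandwich errors
# ---------------------------------------------------------------------------

def _weibull_row_loglik(theta, X, logt, delta, rho_pos):
    """Per-row Weibull AFT log-likelihood at flattened parameters ``theta``.

    lifelines parameterization: S(t) = exp(-(t/lambda)^rho), lambda = exp(X b),
    rho = exp(theta[rho_pos]).
    """
    beta = np.delete(theta, rho_pos)
    rho = np.exp(theta[rho_pos])
    log_lam = X @ beta
    z = np.exp(rho * (logt - log_lam))
    return delta * (np.log(rho) + (rho - 1.0) * logt - rho * log_lam) - z


def fit_weibull_aft(
    clone_frame: pd.DataFrame,
    horizon_days: int,
    covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT,
) -> AFTEstimate:
    """Weibull AFT sensitivity model with subject-clustered robust SEs.

    The point fit is lifelines' weighted MLE; the sandwich B-matrix is built
    from per-row numerical scores at the MLE, summed within subjects, so the
    reported SE accounts for both the estimated weights' heteroscedasticity
    and the duplication of subjects across clones.
    """
    _check_outcome_frame(clone_frame)
    cols = ["duration", "event", "weight", "early", *covariates]
    import warnings
    aft = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pen in (0.0, 1e-3, 1e-2):
            try:
                aft = WeibullAFTFitter(penalizer=pen)
                aft.fit(clone_frame[cols], duration_col="duration",
                        event_col="event", weights_col="weight",
                        show_progress=False)
                break
            except Exception as exc:
                last = exc
                aft = None
        if aft is None:
            raise RuntimeError(f"Weibull AFT did not converge: {last}")

    params = aft.params_  # MultiIndex: (lambda_, covariate...), (rho_, Intercept)
    names = list(params.index)
    rho_pos = names.index(("rho_", "Intercept"))
    lam_covs = [n[1] for n in names if n[0] == "lambda_"]
    design_cols = [c if c != "Intercept" else None for c in lam_covs]
    X = np.column_stack([
        np.ones(len(clone_frame)) if c is None else clone_frame[c].to_numpy(dtype=float)
        for c in design_cols
    ])
    theta = params.to_numpy()
    logt = np.log(clone_frame["duration"].to_numpy(dtype=float))
    delta = clone_frame["event"].to_numpy(dtype=float)
    w = clone_frame["weight"].to_numpy(dtype=float)

    # per-row numerical scores at the MLE
    G = np.empty((len(clone_frame), len(theta)))
    h = 1e-6
    for j in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        G[:, j] = (
            _weibull_row_loglik(tp, X, logt, delta, rho_pos)
            - _weibull_row_loglik(tm, X, logt, delta, rho_pos)
        ) / (2.0 * h)
    G *= w[:, None]
    gc = pd.DataFrame(G).groupby(clone_frame["subject_id"].to_numpy()).sum().to_numpy()
    B = gc.T @ gc
    V = aft.variance_matrix_.to_numpy()
    robust_cov = V @ B @ V

    i_early = names.index(("lambda_", "early"))
    coef = float(theta[i_early])
    se = float(np.sqrt(robust_cov[i_early, i_early]))
    return AFTEstimate(
        acceleration_factor=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959964 * se)),
        ci_high=float(np.exp(coef + 1.959964 * se)),
        p_value=float(2.0 * stats.norm.sf(abs(coef / se))),
        robust_se=se,
        weibull_shape=float(np.exp(theta[rho_pos])),
        horizon_days=horizon_days,
        fitter=aft,
    )


# ---------------------------------------------------------------------------
# survival curves
# ---------------------------------------------------------------------------

def survival_curves(
    clone_frame: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT,
    time_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-arm survival curves, two ways.

    ``weighted_km``: nonparametric product-limit estimate with the truncated
    stabilized weights.  ``cox_adjusted``: survival at the covariate means
    from a weighted Cox model stratified by arm.  Tidy output columns:
    method, arm, time (days), survival, at_risk.
    """
    frames = []
    grid = time_grid
    for arm, sub in clone_frame.groupby("arm"):
        kmf = KaplanMeierFitter()
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kmf.fit(sub["duration"], event_observed=sub["event"],
                    weights=sub["weight"], timeline=grid)
        sf = kmf.survival_function_.iloc[:, 0]
        at_risk = [
            float(sub.loc[sub["duration"] >= t, "weight"].sum()) for t in sf.index
        ]
        frames.append(pd.DataFrame({
            "method": "weighted_km", "arm": arm,
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.to_numpy(), "at_risk": at_risk,
        }))

    if (len(covariates) and len(clone_frame["arm"].unique()) == 2
            and clone_frame["event"].sum() > 0):
        import warnings
        cph = CoxPHFitter()
        cols = ["duration", "event", "weight", "arm", *covariates]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(clone_frame[cols], duration_col="duration", event_col="event",
                    weights_col="weight", strata=["arm"], robust=True)
            mean_row = clone_frame[list(covariates)].mean().to_frame().T
            mean_row["arm"] = None
            for arm in clone_frame["arm"].unique():
                mr = mean_row.copy()
                mr["arm"] = arm
                sf = cph.predict_survival_function(mr)
                frames.append(pd.DataFrame({
                    "method": "cox_adjusted", "arm": arm,
                    "time": sf.index.to_numpy(dtype=float),
                    "survival": sf.iloc[:, 0].to_numpy(),
                    "at_risk": np.nan,
                }))
    return pd.concat(frames, ignore_index=True)
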