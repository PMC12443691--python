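"""Doubly robust (augmented IPW) fixed-horizon mortality risks.

For strategy a the estimator is

    psi_a = (1/n) sum_i [ m_a(X_i) + D_i(a) * sw_i(a) * (Y_i - m_a(X_i)) ]

where Y_i is death by the horizon, D_i(a) indicates adherence to strategy a
through the grace period (a subject dying inside the grace window is adherent
to both strategies), sw_i(a) is the clone's frozen adherence weight, and
m_a(X) is an outcome regression of Y on the arm indicator and time-zero
covariates among adherent clones, fitted with the adherence weights.  The
weight term corrects selection by protocol-deviation censoring when the
treatment-hazard model is right; the outcome model corrects it when the
regression is right.  Confidence intervals come from the empirical influence
function; the risk-difference SE uses the per-subject IF difference, so the
covariance induced by shared subjects is automatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survival import DEFAULT_ADJUSTMENT
from .weights import WeightedClones

__all__ = [
    "RiskEstimate",
    "RiskDifference",
    "OutcomeModel",
    "fit_outcome_model",
    "aipw_risk",
    "aipw_risk_difference",
    "aipw_analysis",
    "adherence_indicator",
    "adherence_weights",
]


@dataclass
class RiskEstimate:
    strategy: str
    horizon_days: int
    risk: float
    ci_low: float
    ci_high: float
    se: float
    influence: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"strategy": self.strategy, "horizon_days": self.horizon_days,
                "risk": self.risk, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "se": self.se}


@dataclass
class RiskDifference:
    rd: float            # percentage points (early minus never)
    ci_low: float
    ci_high: float
    se: float
    horizon_days: int

    def to_dict(self) -> dict:
        return {"rd_pp": self.rd, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "se": self.se, "horizon_days": self.horizon_days}


@dataclass
class OutcomeModel:
    params: np.ndarray
    covariates: tuple[str, ...]
    cov_matrix: np.ndarray = field(repr=False, default=None)
    score_by_subject: pd.DataFrame = field(repr=False, default=None)
    leverage: pd.Series = field(repr=False, default=None)  # per (subject, arm)

    def _design(self, df: pd.DataFrame, early: int) -> np.ndarray:
        cols = [np.ones(len(df)), np.full(len(df), float(early))]
        for c in self.covariates:
            cols.append(df[c].to_numpy(dtype=float))
        return np.column_stack(cols)

    def predict(self, df: pd.DataFrame, strategy: str) -> np.ndarray:
        from scipy.special import expit
        return expit(self._design(df, int(strategy == "early")) @ self.params)


def adherence_indicator(clones: pd.DataFrame, grace_hours: int) -> np.ndarray:
    """D_i(a): adherent to the clone's strategy through the grace period."""
    init = clones["init_offset"].to_numpy(dtype=float)
    death = clones["death_offset"].to_numpy(dtype=float)
    init = np.where(np.isnan(init), np.inf, init)
    death = np.where(np.isnan(death), np.inf, death)
    early = (clones["arm"] == "early").to_numpy()
    died_in_grace = death <= grace_hours
    adherent_early = (init <= grace_hours) | died_in_grace
    adherent_never = (init > grace_hours) | died_in_grace | (death <= init)
    return np.where(early, adherent_early, adherent_never)


def _horizon_death(clones: pd.DataFrame, horizon_days: int) -> np.ndarray:
    death = clones["death_offset"].to_numpy(dtype=float)
    death = np.where(np.isnan(death), np.inf, death)
    return (death <= horizon_days * 24.0).astype(float)


def adherence_weights(
    clones: pd.DataFrame, grace_hours: int,
    truncation_percentiles: tuple[float, float] = (1.0, 99.0),
) -> np.ndarray:
    """Inverse-probability-of-adherence weight per clone row.

    Unstabilized propensities, so that each adherence class carries its
    strategy-consistent probability mass (a numerator tilt would re-weight
    grace-period deaths against treated survivors): a subject dying inside
    the grace window could not have deviated from either strategy, hence
    weight 1; a treated survivor in the early arm is weighted by the inverse
    probability of initiating within grace given the covariate path; a
    never-arm clone by the inverse probability of remaining untreated over
    its observed risk hours.  The final estimator Hajek-normalises, so the
    weights only need to be proportional within arm.
    """
    death = clones["death_offset"].to_numpy(dtype=float)
    death = np.where(np.isnan(death), np.inf, death)
    early = (clones["arm"] == "early").to_numpy()
    if "p_init_grace_den" not in clones.columns:
        # fall back on the frozen stabilized weights when the integrated
        # propensities were not computed
        return clones["sw_trunc_final"].to_numpy(dtype=float).copy()
    w_never = 1.0 / clones["p_stay_untreated_den"].to_numpy(dtype=float)
    w_early = 1.0 / clones["p_init_grace_den"].to_numpy(dtype=float)
    # an early-arm clone dying in grace is adherent under ANY initiation
    # pattern, so its adherence propensity is 1; a never-arm grace death still
    # carries the inverse probability of its observed untreated hours
    w = np.where(early, np.where(death <= grace_hours, 1.0, w_early), w_never)
    lo, hi = np.percentile(w, truncation_percentiles)
    return np.clip(w, lo, hi)


def fit_outcome_model(
    weighted: WeightedClones,
    horizon_days: int,
    grace_hours: int,
    covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT,
) -> OutcomeModel:
    """Weighted logistic regression of death-by-horizon on arm + time-zero
    covariates among clones adherent to their assigned strategy."""
    clones = weighted.clones
    D = adherence_indicator(clones, grace_hours)
    aw = adherence_weights(clones, grace_hours)
    sub = clones[D].copy()
    if len(sub) == 0:
        raise ValueError("no adherent clones to fit the outcome model on")
    y = _horizon_death(sub, horizon_days)
    w = aw[D]
    if y.min() == y.max():
        # degenerate: every adherent clone shares the outcome; the model is a
        # constant and carries no estimable covariate information
        const = np.zeros(2 + len(covariates))
        const[0] = 15.0 if y.min() == 1.0 else -15.0
        return OutcomeModel(params=const, covariates=tuple(covariates))
    X = np.column_stack(
        [np.ones(len(sub)), (sub["arm"] == "early").to_numpy().astype(float)]
        + [sub[c].to_numpy(dtype=float) for c in covariates]
    )
    # ridge-stabilised weighted logistic; the intercept and the arm indicator
    # are never penalised, so the strategy contrast itself is not shrunk
    from scipy.special import expit
    from .weights import DEFAULT_RIDGE, ridge_logistic
    params, _ = ridge_logistic(X, y, sample_weight=w, unpenalized=2)

    # penalised observed information and per-subject score sums, needed by the
    # risk estimator's nuisance-estimation variance term
    mu = expit(X @ params)
    scales = X.std(axis=0)
    scales[:2] = 0.0
    H = (X.T * (w * mu * (1 - mu))) @ X + 2.0 * DEFAULT_RIDGE * np.diag(scales ** 2)
    scores = X * (w * (y - mu))[:, None]
    score_df = pd.DataFrame(scores).groupby(sub["subject_id"].to_numpy()).sum()
    H_inv = np.linalg.inv(H)
    # per-row leverage of the weighted fit, for the HC3-style residual
    # inflation in the influence-function variance
    v = w * mu * (1 - mu)
    lev = pd.Series(
        np.clip(v * np.einsum("ij,jk,ik->i", X, H_inv, X), 0.0, 0.95),
        index=pd.MultiIndex.from_arrays([sub["subject_id"], sub["arm"]]),
    )
    return OutcomeModel(params=params, covariates=tuple(covariates),
                        cov_matrix=H_inv, score_by_subject=score_df,
                        leverage=lev)


def aipw_risk(
    weighted: WeightedClones,
    outcome: OutcomeModel,
    strategy: str,
    horizon_days: int,
    grace_hours: int,
) -> RiskEstimate:
    """Augmented IPW risk of death by the horizon under one strategy."""
    if strategy not in ("early", "never"):
        raise ValueError(f"unknown strategy {strategy!r}")
    clones = weighted.clones
    arm_rows = clones[clones["arm"] == strategy].reset_index(drop=True)
    D = adherence_indicator(arm_rows, grace_hours).astype(float)
    if D.sum() == 0:
        raise ValueError(f"zero adherent subjects for strategy {strategy!r}")
    sw = adherence_weights(arm_rows, grace_hours)
    Y = _horizon_death(arm_rows, horizon_days)
    m = outcome.predict(arm_rows, strategy)
    # Hajek-normalised augmentation: the adherence weights of one arm sum to
    # the marginal probability of that adherence pattern, not to n, so the
    # weighted residual is renormalised by the realised weight mass.
    b = D * sw
    a = b * (Y - m)
    B = float(b.mean())
    R = float(a.mean()) / B
    psi = float(m.mean()) + R

    # HC3-style residual inflation: the outcome model is fitted on the same
    # adherent rows the residual term averages over, and with few rows per
    # parameter the in-sample residuals are shrunk by (1 - leverage)
    resid = Y - m
    if outcome.leverage is not None:
        key = pd.MultiIndex.from_arrays(
            [arm_rows["subject_id"], arm_rows["arm"]])
        h = outcome.leverage.reindex(key).fillna(0.0).to_numpy()
        resid = resid / (1.0 - h)
    a_v = b * resid
    infl = (m - m.mean()) + (a_v - R * b) / B
    if outcome.cov_matrix is not None and outcome.score_by_subject is not None:
        # first-order contribution of the estimated outcome coefficients
        X_a = outcome._design(arm_rows, int(strategy == "early"))
        dm = (m * (1 - m))[:, None] * X_a
        g = dm.mean(axis=0) - (b[:, None] * dm).sum(axis=0) / (B * len(arm_rows))
        proj = outcome.cov_matrix @ g
        corr = outcome.score_by_subject.reindex(
            arm_rows["subject_id"]).fillna(0.0).to_numpy() @ proj
        infl = infl + corr
    se = float(infl.std(ddof=1) / np.sqrt(len(infl)))
    return RiskEstimate(
        strategy=strategy, horizon_days=horizon_days,
        risk=psi,
        ci_low=max(psi - 1.959964 * se, 0.0),
        ci_high=min(psi + 1.959964 * se, 1.0),
        se=se, influence=infl,
    )


def aipw_risk_difference(
    risk_early: RiskEstimate, risk_never: RiskEstimate
) -> RiskDifference:
    """Risk difference (early minus never) in percentage points.

    Both estimates must be computed on the same subjects and horizon; the SE
    uses the per-subject influence-function difference, which carries the
    cross-strategy covariance.
    """
    if risk_early.horizon_days != risk_never.horizon_days:
        raise ValueError("risk estimates have mismatched horizons")
    if risk_early.influence is None or risk_never.influence is None or \
            len(risk_early.influence) != len(risk_never.influence):
        raise ValueError("risk estimates must carry aligned influence functions")
    diff = risk_early.influence - risk_never.influence
    rd = risk_early.risk - risk_never.risk
    se = float(diff.std(ddof=1) / np.sqrt(len(diff)))
    return RiskDifference(
        rd=rd * 100.0,
        ci_low=(rd - 1.959964 * se) * 100.0,
        ci_high=(rd + 1.959964 * se) * 100.0,
        se=se * 100.0,
        horizon_days=risk_early.horizon_days,
    )


def aipw_analysis(
    weighted: WeightedClones,
    horizon_days: int,
    grace_hours: int,
    covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT,
) -> tuple[RiskEstimate, RiskEstimate, RiskDifference]:
    """Convenience wrapper: outcome model, both strategy risks, and their
    difference at one horizon."""
    outcome = fit_outcome_model(weighted, horizon_days, grace_hours, covariates)
    r_early = aipw_risk(weighted, outcome, "early", horizon_days, grace_hours)
    r_never = aipw_risk(weighted, outcome, "never", horizon_days, grace_hours)
    return r_early, r_never, aipw_risk_difference(r_early, r_never)
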