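"""Treatment-hazard models and stabilized inverse-probability-of-censoring weights.

The artificial censoring of the clone-censor design is informative: sicker
subjects initiate RRT earlier, so the never-initiate arm selectively loses
sick person-time and the early arm selectively keeps it.  A pooled
discrete-time logistic model of P(initiate RRT in hour t | covariates, not yet
initiated) supplies denominator probabilities; a marginal model (time since
eligibility only, as a natural cubic spline) supplies the stabilizing
numerator.  Each clone-hour receives the cumulative product of
numerator/denominator probabilities of the adherence it actually displayed —
(1 - p) factors while remaining untreated, a p factor at the initiation hour
in the early arm — and the weight freezes once the clone's strategy is fully
resolved (early arm after initiation, both arms at the end of grace).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import WeightModelSpec

__all__ = [
    "WeightModelError",
    "TreatmentHazardModel",
    "build_initiation_risk_table",
    "fit_treatment_hazard_model",
    "fit_weight_models",
    "compute_stabilized_ipw",
    "WeightedClones",
    "smd_balance",
    "balance_report",
    "vif_table",
    "natural_cubic_spline_basis",
]


class WeightModelError(RuntimeError):
    pass


#: weakly-informative ridge on standardized coefficients (prior sd ~0.5 on the
#: standardized log-odds scale); an absolute penalty, so its influence on the
#: fit vanishes as the person-time likelihood grows
DEFAULT_RIDGE = 2.0


def ridge_logistic(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    penalty: float = DEFAULT_RIDGE,
    unpenalized: int = 1,
    maxiter: int = 60,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Logistic MLE with an absolute ridge penalty on standardized coefficients.

    ``unpenalized`` leading columns (the intercept) carry no penalty; the
    remaining coefficients are penalised on the scale of their column's SD, so
    the penalty is invariant to the units of the covariates.  Returns
    (params, standard errors from the penalised observed information).
    """
    from scipy.special import expit as _expit

    n, p = X.shape
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    scales = X.std(axis=0)
    scales[:unpenalized] = 0.0
    D = 2.0 * penalty * np.diag(scales ** 2)
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-10) / max(1 - y.mean(), 1e-10))
    for _ in range(maxiter):
        eta = X @ beta
        mu = _expit(eta)
        v = w * mu * (1 - mu)
        grad = X.T @ (w * (y - mu)) - D @ beta
        H = (X.T * v) @ X + D
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise WeightModelError(f"singular information matrix: {exc}") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    if not np.all(np.isfinite(beta)):
        raise WeightModelError("non-finite coefficients (possible separation)")
    cov = np.linalg.inv((X.T * (w * _expit(X @ beta) * (1 - _expit(X @ beta)))) @ X + D)
    return beta, np.sqrt(np.diag(cov))


def natural_cubic_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond boundary knots).

    ``knots`` are the K >= 3 knot locations (boundary + internal); the basis
    has K - 1 columns: x itself plus K - 2 truncated-cubic contrasts.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(knots, dtype=float)
    K = len(k)

    def d(j):
        return (np.maximum(x - k[j], 0.0) ** 3 - np.maximum(x - k[-1], 0.0) ** 3) / (
            k[-1] - k[j]
        )

    cols = [x]
    for j in range(K - 2):
        cols.append(d(j) - d(K - 2))
    return np.column_stack(cols)


def build_initiation_risk_table(
    eligible: pd.DataFrame, panel: pd.DataFrame, grace_hours: int,
    until_initiation: bool = True,
) -> pd.DataFrame:
    """Person-hours at risk of RRT initiation, hours 1..grace since time zero.

    A subject contributes hour h while untreated entering the hour and alive
    through it; the covariate snapshot is taken at the start of the interval
    (absolute hour t0 + h - 1).  ``initiated`` marks the hour RRT begins.
    With ``until_initiation=False`` rows continue past the initiation hour
    while the subject is alive — the prediction grid used to integrate each
    subject's probability of initiating within the grace window.
    """
    t0 = eligible["time_zero_hour"].to_numpy(dtype=float)
    init = eligible["init_offset"].to_numpy(dtype=float)
    death = eligible["death_offset"].to_numpy(dtype=float)
    init = np.where(np.isnan(init), np.inf, init)
    death = np.where(np.isnan(death), np.inf, death)

    n_rows = np.minimum.reduce([
        np.full(len(eligible), float(grace_hours)),
        init if until_initiation else np.full(len(eligible), np.inf),
        np.where(death > grace_hours, np.inf, death - 1),
    ]).astype(int)
    n_rows = np.maximum(n_rows, 0)
    if n_rows.sum() == 0:
        raise WeightModelError("empty initiation risk set")

    ridx = np.repeat(np.arange(len(eligible)), n_rows)
    h = np.concatenate([np.arange(1, c + 1) for c in n_rows]).astype(float)
    tab = pd.DataFrame({
        "subject_id": eligible["subject_id"].to_numpy()[ridx],
        "hours_since_eligibility": h,
        "abs_hour": t0[ridx] + h - 1.0,
        "initiated": (h == init[ridx]).astype(int),
    })
    for col in ("age", "female", "cci", "sepsis", "vasopressor", "mech_vent",
                "time_zero_hour"):
        tab[col] = eligible[col].to_numpy()[ridx]

    time_varying = [c for c in ("sofa", "heart_rate", "resp_rate", "dbp", "spo2",
                                "sbp", "mbp", "lactate", "creatinine")
                    if c in panel.columns]
    pan = panel[["subject_id", "hour"] + time_varying].rename(columns={"hour": "abs_hour"})
    tab = tab.merge(pan, on=["subject_id", "abs_hour"], how="left")
    return tab


@dataclass
class TreatmentHazardModel:
    """Fitted pooled logistic hazard of RRT initiation."""

    params: pd.Series
    covariates: tuple[str, ...]
    spline_knots: np.ndarray
    coef_table: pd.DataFrame = field(repr=False, default=None)

    def design(self, df: pd.DataFrame) -> np.ndarray:
        spline = natural_cubic_spline_basis(
            df["hours_since_eligibility"].to_numpy(), self.spline_knots
        )
        cols = [np.ones(len(df)), *spline.T]
        for c in self.covariates:
            cols.append(df[c].to_numpy(dtype=float))
        return np.column_stack(cols)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit
        return expit(self.design(df) @ self.params.to_numpy())


def fit_treatment_hazard_model(
    risk_table: pd.DataFrame, spec: WeightModelSpec, covariates: tuple[str, ...] | None = None
) -> TreatmentHazardModel:
    """Fit the pooled discrete-time logistic initiation model.

    ``covariates=None`` uses the spec's denominator set; pass
    ``spec.numerator_covariates`` (possibly empty) for the stabilizing
    numerator, which always retains the time spline and intercept.
    """
    covs = spec.denominator_covariates if covariates is None else tuple(covariates)
    if len(risk_table) == 0 or risk_table["initiated"].sum() == 0:
        raise WeightModelError("empty risk set or no initiation events")
    for c in covs:
        if risk_table[c].isna().any():
            raise WeightModelError(f"missing values in weight-model covariate {c!r}")

    h = risk_table["hours_since_eligibility"].to_numpy()
    qs = np.quantile(h, [0.0, 0.25, 0.50, 0.75, 1.0])
    knots = np.unique(qs)
    if len(knots) < 3:
        knots = np.array([h.min(), (h.min() + h.max()) / 2.0, h.max() + 1.0])

    shell = TreatmentHazardModel(
        params=None, covariates=covs, spline_knots=knots)
    X = shell.design(risk_table)
    names = ["intercept"] + [f"time_spline_{i}" for i in range(len(knots) - 1)] + list(covs)
    y = risk_table["initiated"].to_numpy()

    y1 = y == 1
    for j, c in enumerate(covs):
        x = X[:, len(knots) + j]
        if x.std() == 0:
            raise WeightModelError(f"covariate {c!r} has no variation")
        if x[y1].size and (x[y1].min() > x[~y1].max() or x[y1].max() < x[~y1].min()):
            raise WeightModelError(f"complete separation on covariate {c!r}")

    n_spline = len(knots) - 1
    coefs, bse = ridge_logistic(X, y.astype(float), unpenalized=1 + n_spline)
    from scipy import stats as _st
    z = np.divide(coefs, bse, out=np.zeros_like(coefs), where=bse > 0)
    params = pd.Series(coefs, index=names)
    coef_table = pd.DataFrame({
        "coef": coefs, "se": bse, "z": z, "p": 2 * _st.norm.sf(np.abs(z)),
    }, index=names)
    return TreatmentHazardModel(
        params=params, covariates=covs, spline_knots=knots, coef_table=coef_table
    )


def fit_weight_models(
    risk_table: pd.DataFrame, spec: WeightModelSpec
) -> tuple[TreatmentHazardModel, TreatmentHazardModel]:
    """(denominator, numerator) hazard models for the stabilized weights."""
    den = fit_treatment_hazard_model(risk_table, spec)
    num = fit_treatment_hazard_model(risk_table, spec, covariates=spec.numerator_covariates)
    return den, num


@dataclass
class WeightedClones:
    """Clone table and clone-hour person-time augmented with weights."""

    clones: pd.DataFrame            # + sw_final, sw_trunc_final
    person_time: pd.DataFrame       # clone-hour rows through grace with sw
    truncation_bounds: tuple[float, float]
    risk_table: pd.DataFrame

    @property
    def mean_sw(self) -> float:
        return float(self.person_time["sw"].mean())


def compute_stabilized_ipw(
    clones: pd.DataFrame,
    risk_table: pd.DataFrame,
    denominator: TreatmentHazardModel,
    numerator: TreatmentHazardModel,
    grace_hours: int,
    truncation_percentiles: tuple[float, float] = (1.0, 99.0),
    full_risk_table: pd.DataFrame | None = None,
) -> WeightedClones:
    """Attach hourly stabilized weights to every clone-hour through grace.

    The hour-h weight multiplies, over adherent hours j <= h, the ratio of
    numerator to denominator probabilities of the observed adherence: (1 - p)
    ratios while untreated, the p ratio at the initiation hour in the early
    arm.  A row on which the clone is artificially censored keeps the weight
    it carried entering the interval.  After resolution the weight is frozen;
    ``sw_final`` / ``sw_trunc_final`` are the frozen per-clone weights used by
    the outcome models.
    """
    G = int(grace_hours)
    p_d = denominator.predict(risk_table)
    p_n = numerator.predict(risk_table)
    for name, p in (("denominator", p_d), ("numerator", p_n)):
        if np.any((p <= 0.0) | (p >= 1.0)):
            raise WeightModelError(
                f"{name} fitted probability of 0 or 1; truncate or respecify the model"
            )

    subjects = clones["subject_id"].drop_duplicates().to_numpy()
    n = len(subjects)
    pos = pd.Series(np.arange(n), index=subjects)
    si = pos[risk_table["subject_id"]].to_numpy()
    hj = risk_table["hours_since_eligibility"].to_numpy().astype(int) - 1

    factor_no = np.ones((n, G))
    ratio_yes = np.full((n, G), np.nan)
    factor_no[si, hj] = (1.0 - p_n) / (1.0 - p_d)
    ratio_yes[si, hj] = p_n / p_d
    # prefix products with a leading 1 column: P[:, j] = prod of factors 1..j
    P = np.concatenate([np.ones((n, 1)), np.cumprod(factor_no, axis=1)], axis=1)

    meta = clones.drop_duplicates("subject_id").set_index("subject_id")
    init = meta["init_offset"].reindex(subjects).to_numpy(dtype=float)
    init = np.where(np.isnan(init), np.inf, init)

    # clone-hour person-time through grace
    pieces = []
    for arm in ("early", "never"):
        arm_rows = clones[clones["arm"] == arm].set_index("subject_id")
        exit_ = arm_rows["exit_offset"].reindex(subjects).to_numpy(dtype=float)
        n_h = np.ceil(np.minimum(exit_, float(G))).astype(int)
        n_h = np.maximum(n_h, 1)  # a clone censored at hour 0+ still has its first row
        ridx = np.repeat(np.arange(n), n_h)
        hours = np.concatenate([np.arange(1, c + 1) for c in n_h])
        cap = np.minimum(hours, np.where(np.isfinite(init[ridx]),
                                         init[ridx] - 1, float(G))).astype(int)
        sw = P[ridx, np.minimum(cap, G)]
        if arm == "early":
            treated = hours >= init[ridx]
            yes_idx = np.clip(init[ridx], 1, G).astype(int) - 1
            sw_treated = P[ridx, np.clip(init[ridx] - 1, 0, G).astype(int)] * \
                ratio_yes[ridx, yes_idx]
            sw = np.where(treated & np.isfinite(init[ridx]), sw_treated, sw)
            # censored exactly at grace end without initiating: weight entering
            at_grace_censor = (hours == G) & (init[ridx] > G)
            sw = np.where(at_grace_censor, P[ridx, G - 1], sw)
        pieces.append(pd.DataFrame({
            "subject_id": subjects[ridx], "arm": arm, "hour": hours.astype(float),
            "sw": sw,
        }))
    person_time = pd.concat(pieces, ignore_index=True)
    if not np.all(person_time["sw"] > 0):
        raise WeightModelError("nonpositive stabilized weight encountered")

    lo, hi = np.percentile(person_time["sw"], truncation_percentiles)
    person_time["sw_trunc"] = person_time["sw"].clip(lo, hi)

    # frozen per-clone weights at strategy resolution
    final = person_time.groupby(["subject_id", "arm"], sort=False)["sw"].last()
    out = clones.copy()
    key = pd.MultiIndex.from_arrays([out["subject_id"], out["arm"]])
    out["sw_final"] = final.reindex(key).to_numpy()
    out["sw_trunc_final"] = np.clip(out["sw_final"], lo, hi)

    # attach fitted probabilities to the risk table for diagnostics
    rt = risk_table.copy()
    rt["p_denominator"] = p_d
    rt["p_numerator"] = p_n
    pt_key = pd.MultiIndex.from_arrays(
        [person_time["subject_id"], person_time["hour"]])
    rt_prob = rt.set_index(["subject_id", "hours_since_eligibility"])
    person_time["p_denominator"] = rt_prob["p_denominator"].reindex(pt_key).to_numpy()
    person_time["p_numerator"] = rt_prob["p_numerator"].reindex(pt_key).to_numpy()

    # per-subject probability of remaining untreated over the observed risk
    # rows under the denominator model (the never-arm adherence propensity)
    stay = pd.Series(np.log1p(-p_d)).groupby(risk_table["subject_id"].to_numpy()).sum()
    out["p_stay_untreated_den"] = np.exp(
        stay.reindex(out["subject_id"]).fillna(0.0).to_numpy())

    # per-subject probability of initiating within grace under both models,
    # integrated over the full alive person-hour grid (used by the AIPW
    # adherence propensities)
    if full_risk_table is not None:
        fp_d = denominator.predict(full_risk_table)
        fp_n = numerator.predict(full_risk_table)
        surv_d = pd.Series(np.log1p(-fp_d)).groupby(
            full_risk_table["subject_id"].to_numpy()).sum()
        surv_n = pd.Series(np.log1p(-fp_n)).groupby(
            full_risk_table["subject_id"].to_numpy()).sum()
        out["p_init_grace_den"] = 1.0 - np.exp(
            surv_d.reindex(out["subject_id"]).fillna(0.0).to_numpy())
        out["p_init_grace_num"] = 1.0 - np.exp(
            surv_n.reindex(out["subject_id"]).fillna(0.0).to_numpy())

    return WeightedClones(
        clones=out, person_time=person_time,
        truncation_bounds=(float(lo), float(hi)), risk_table=rt,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def smd_balance(
    table: pd.DataFrame,
    covariates: list[str],
    weights: np.ndarray | None = None,
    group_col: str = "arm",
    reference_level: str = "early",
) -> pd.DataFrame:
    """Standardized mean differences between the two groups.

    SMD = (weighted mean_1 - weighted mean_0) / sqrt((s1^2 + s0^2) / 2) with
    *unweighted* per-group standard deviations, so before/after comparisons
    share a denominator.  Zero pooled SD yields SMD 0 when the means agree and
    NaN (flagged ``undefined``) otherwise.
    """
    levels = table[group_col].unique()
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, found {list(levels)}")
    g1 = table[group_col] == reference_level
    if g1.sum() == 0 or (~g1).sum() == 0:
        raise ValueError("both groups must be nonempty")
    w = np.ones(len(table)) if weights is None else np.asarray(weights, dtype=float)

    rows = []
    for c in covariates:
        x = table[c].to_numpy(dtype=float)
        m1 = np.average(x[g1], weights=w[g1])
        m0 = np.average(x[~g1], weights=w[~g1])
        s1, s0 = x[g1].std(ddof=1), x[~g1].std(ddof=1)
        denom = np.sqrt((s1 ** 2 + s0 ** 2) / 2.0)
        if denom == 0:
            smd, undefined = (0.0, False) if m1 == m0 else (np.nan, True)
        else:
            smd, undefined = (m1 - m0) / denom, False
        rows.append({"covariate": c, "smd": smd, "undefined": undefined})
    return pd.DataFrame(rows)


def balance_report(
    table: pd.DataFrame,
    covariates: list[str],
    weights: np.ndarray,
    group_col: str = "arm",
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Before/after-weighting SMDs against the |SMD| < 0.1 balance criterion."""
    before = smd_balance(table, covariates, None, group_col)
    after = smd_balance(table, covariates, weights, group_col)
    rep = before.rename(columns={"smd": "smd_before"}).drop(columns="undefined")
    rep["smd_after"] = after["smd"].to_numpy()
    rep["balanced"] = rep["smd_after"].abs() < threshold
    return rep


def vif_table(X: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factor per covariate: VIF_j = 1 / (1 - R^2_j) from
    regressing covariate j on the others (with intercept).  Perfectly collinear
    covariates get VIF = inf with a named warning."""
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("need at least two covariates for VIFs")
    if len(X) <= len(cols):
        raise ValueError("need more rows than covariates")
    M = X.to_numpy(dtype=float)
    rows = []
    for j, c in enumerate(cols):
        y = M[:, j]
        A = np.column_stack([np.ones(len(M)), np.delete(M, j, axis=1)])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        tss = np.sum((y - y.mean()) ** 2)
        r2 = 0.0 if tss == 0 else 1.0 - resid @ resid / tss
        if r2 > 1.0 - 1e-12:
            warnings.warn(f"covariate {c!r} is perfectly collinear; VIF is infinite")
            vif = np.inf
        else:
            vif = max(1.0 / (1.0 - r2), 1.0)
        rows.append({"covariate": c, "vif": vif})
    return pd.DataFrame(rows)
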