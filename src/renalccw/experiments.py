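"""Replicate-level experiment drivers.

Thin wrappers that run one simulated cohort through the clone-censor-weight
pipeline and return the handful of numbers the calibration and recovery
studies need.  Shared by the test suite, the analysis scripts and the
acceptance script so that every study exercises exactly the same code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import aipw as aipw_mod
from . import survival as surv
from .cohort import apply_eligibility
from .config import (
    EligibilityCriteria,
    SimConfig,
    WeightModelSpec,
)
from .emulation import apply_protocol_censoring, clone_subjects
from .pipeline import prepare_cohort
from .simulate import (
    GroundTruth,
    _build_cohort,
    _factual_outcomes,
    _simulate_paths,
    _truth_from_paths,
    inject_missingness,
)
from .weights import (
    build_initiation_risk_table,
    compute_stabilized_ipw,
    fit_treatment_hazard_model,
)

__all__ = ["ReplicateResult", "ccw_replicate"]


@dataclass
class ReplicateResult:
    n_eligible: int
    truth: GroundTruth
    hr: float = np.nan
    hr_ci: tuple = (np.nan, np.nan)
    naive_hr: float = np.nan
    rd: float = np.nan                  # AIPW risk difference, percentage points
    rd_ci: tuple = (np.nan, np.nan)
    risk_early: float = np.nan
    risk_never: float = np.nan
    af: float = np.nan
    af_ci: tuple = (np.nan, np.nan)
    weibull_shape: float = np.nan
    mean_sw: float = np.nan
    max_abs_smd_after: float = np.nan
    max_abs_smd_before: float = np.nan
    max_vif: float = np.nan


def ccw_replicate(
    config: SimConfig,
    min_stage: int = 1,
    horizon_days: int = 90,
    do_cox: bool = True,
    do_aipw: bool = True,
    do_naive: bool = False,
    do_aft: bool = False,
    do_balance: bool = False,
    omit_from_ps: tuple[str, ...] = (),
    omit_from_outcome: tuple[str, ...] = (),
) -> ReplicateResult:
    """One simulated cohort through screen -> clone -> censor -> weight ->
    estimate, with optional deliberate misspecification of either nuisance
    model (covariates dropped from the treatment-hazard or outcome model)."""
    grace = config.grace_hours
    paths = _simulate_paths(config)
    init, death = _factual_outcomes(paths)
    cohort = _build_cohort(paths, init, death)
    if config.missing_rates:
        cohort, _ = inject_missingness(cohort, config.missing_rates,
                                       seed=config.seed + 1)
        cohort = prepare_cohort(cohort, seed=config.seed + 2)
    criteria = EligibilityCriteria(min_aki_stage=min_stage)
    eligible, _ = apply_eligibility(cohort, criteria)
    truth = _truth_from_paths(
        paths,
        eligible["time_zero_hour"].to_numpy(dtype=float),
        eligible["subject_id"].to_numpy(),
    )
    res = ReplicateResult(n_eligible=len(eligible), truth=truth)
    if len(eligible) == 0:
        return res

    spec = WeightModelSpec()
    ps_covs = tuple(c for c in spec.denominator_covariates if c not in omit_from_ps)
    out_covs = tuple(c for c in surv.DEFAULT_ADJUSTMENT
                     if c not in omit_from_outcome)

    clones = apply_protocol_censoring(
        clone_subjects(eligible, grace), grace, horizon_days=90)
    rt = build_initiation_risk_table(eligible, cohort.panel, grace)
    frt = build_initiation_risk_table(eligible, cohort.panel, grace,
                                      until_initiation=False)
    den = fit_treatment_hazard_model(rt, spec, covariates=ps_covs)
    num = fit_treatment_hazard_model(rt, spec,
                                     covariates=spec.numerator_covariates)
    weighted = compute_stabilized_ipw(
        clones, rt, den, num, grace,
        truncation_percentiles=spec.truncation_percentiles,
        full_risk_table=frt,
    )
    res.mean_sw = weighted.mean_sw

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if do_cox:
            intervals = surv.build_cox_intervals(weighted, grace, horizon_days,
                                                 covariates=out_covs)
            est = surv.fit_weighted_cox(intervals, horizon_days,
                                        covariates=out_covs)
            res.hr, res.hr_ci = est.hr, (est.ci_low, est.ci_high)
        if do_naive:
            nv = surv.fit_naive_cox(eligible, horizon_days)
            res.naive_hr = nv.hr
        if do_aipw:
            outcome = aipw_mod.fit_outcome_model(weighted, horizon_days, grace,
                                                 covariates=out_covs)
            r_e = aipw_mod.aipw_risk(weighted, outcome, "early", horizon_days,
                                     grace)
            r_n = aipw_mod.aipw_risk(weighted, outcome, "never", horizon_days,
                                     grace)
            rd = aipw_mod.aipw_risk_difference(r_e, r_n)
            res.rd, res.rd_ci = rd.rd, (rd.ci_low, rd.ci_high)
            res.risk_early, res.risk_never = r_e.risk, r_n.risk
        if do_aft:
            frame = surv.build_clone_frame(weighted, horizon_days,
                                           covariates=out_covs)
            aft = surv.fit_weibull_aft(frame, horizon_days, covariates=out_covs)
            res.af, res.af_ci = aft.acceleration_factor, (aft.ci_low, aft.ci_high)
            res.weibull_shape = aft.weibull_shape
        if do_balance:
            from .config import WEIGHT_DENOMINATOR_COVARIATES
            from .weights import balance_report, vif_table
            D = aipw_mod.adherence_indicator(weighted.clones, grace)
            aw = aipw_mod.adherence_weights(weighted.clones, grace)
            bal = balance_report(
                weighted.clones[D], list(WEIGHT_DENOMINATOR_COVARIATES), aw[D])
            res.max_abs_smd_after = float(bal["smd_after"].abs().max())
            res.max_abs_smd_before = float(bal["smd_before"].abs().max())
            res.max_vif = float(
                vif_table(eligible[list(WEIGHT_DENOMINATOR_COVARIATES)])["vif"].max())
    return res
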