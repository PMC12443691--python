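import numpy as np
import pandas as pd
import pytest

from renalccw import (
    apply_eligibility,
    apply_protocol_censoring,
    clone_subjects,
    null_scenario,
    simulate_cohort,
)
from renalccw.config import EligibilityCriteria, WeightModelSpec
from renalccw.weights import (
    build_initiation_risk_table,
    compute_stabilized_ipw,
    fit_weight_models,
)


def make_eligible_frame(rows):
    """Hand-built eligible-subject frame.

    ``rows``: list of dicts with subject_id, init_offset, death_offset and
    optional covariates; fills the standard covariate columns with benign
    defaults so downstream builders work.
    """
    defaults = {
        "time_zero_hour": 0.0, "aki_stage_at_t0": 1,
        "age": 65.0, "female": 0, "cci": 7, "sepsis": 1, "mech_vent": 0,
        "vasopressor": 0, "hospital_pre_hours": 24.0, "icu_discharge_hour": 120.0,
        "sofa": 8.0, "heart_rate": 87.0, "resp_rate": 20.0, "sbp": 113.0,
        "dbp": 60.0, "mbp": 78.0, "temperature": 36.9, "spo2": 97.0,
        "ph": 7.37, "bicarbonate": 22.0, "lactate": 2.0, "hemoglobin": 9.0,
        "urea_nitrogen": 39.0, "creatinine": 2.0, "kdigo_stage": 1,
        "init_offset": np.nan, "death_offset": np.nan, "race": "white",
    }
    out = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        out.append(d)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 600-subject null-effect cohort (complete data)."""
    return simulate_cohort(null_scenario(600, 42, missing_rates={}))


@pytest.fixture(scope="session")
def midsize_weighted():
    """A full clone-censor-weight run on a 2,500-subject null cohort,
    shared across weight/survival/AIPW tests."""
    cohort = simulate_cohort(null_scenario(2500, 7, missing_rates={}))
    eligible, _ = apply_eligibility(cohort, EligibilityCriteria(min_aki_stage=1))
    clones = clone_subjects(eligible, 72)
    clones = apply_protocol_censoring(clones, 72, horizon_days=90)
    rt = build_initiation_risk_table(eligible, cohort.panel, 72)
    frt = build_initiation_risk_table(eligible, cohort.panel, 72,
                                      until_initiation=False)
    den, num = fit_weight_models(rt, WeightModelSpec())
    weighted = compute_stabilized_ipw(clones, rt, den, num, 72,
                                      full_risk_table=frt)
    return {
        "cohort": cohort, "eligible": eligible, "weighted": weighted,
        "den": den, "num": num, "risk_table": rt,
    }
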