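"""Treatment-hazard model, stabilized weights, balance and VIF diagnostics."""

import numpy as np
import pandas as pd
import pytest

from renalccw import (
    apply_eligibility,
    apply_protocol_censoring,
    clone_subjects,
    null_scenario,
    simulate_cohort,
    smd_balance,
    vif_table,
)
from renalccw.config import EligibilityCriteria, WeightModelSpec
from renalccw.weights import (
    WeightModelError,
    build_initiation_risk_table,
    compute_stabilized_ipw,
    fit_treatment_hazard_model,
    natural_cubic_spline_basis,
)
from tests.conftest import make_eligible_frame


class TestSplineBasis:
    def test_linear_beyond_boundary_knots(self):
        knots = np.array([0.0, 10.0, 20.0, 30.0])
        x = np.linspace(35.0, 60.0, 40)
        B = natural_cubic_spline_basis(x, knots)
        for j in range(B.shape[1]):
            slopes = np.diff(B[:, j]) / np.diff(x)
            assert np.allclose(slopes, slopes[0], atol=1e-9)

    def test_column_count(self):
        knots = np.array([1.0, 18.0, 36.0, 54.0, 72.0])
        B = natural_cubic_spline_basis(np.arange(1.0, 73.0), knots)
        assert B.shape == (72, len(knots) - 1)


def _flat_risk_table(n_per_hour=200, hours=(1, 2, 3, 4, 5), rate=0.3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for h in hours:
        init = np.zeros(n_per_hour, dtype=int)
        init[: int(rate * n_per_hour)] = 1
        rng.shuffle(init)
        for i, y in enumerate(init):
            rows.append({"subject_id": 10_000 * h + i,
                         "hours_since_eligibility": float(h), "initiated": y})
    return pd.DataFrame(rows)


class TestTreatmentHazardModel:
    def test_covariate_free_rate_recovery(self):
        """With no covariates and a constant 30% hourly initiation rate the
        pooled logistic model reproduces the empirical proportion."""
        rt = _flat_risk_table(rate=0.3)
        model = fit_treatment_hazard_model(rt, WeightModelSpec(), covariates=())
        p = model.predict(rt)
        assert np.allclose(p, 0.30, atol=1e-6)

    def test_simulator_coefficient_recovery(self):
        """The fitted SOFA coefficient recovers the generator's +0.3 within
        two standard errors."""
        cfg = null_scenario(4000, 31, missing_rates={}).with_(
            baseline_coefs={"sofa": 0.3, "sepsis": 0.55, "age": 0.010})
        cohort = simulate_cohort(cfg)
        eligible, _ = apply_eligibility(cohort, EligibilityCriteria())
        rt = build_initiation_risk_table(eligible, cohort.panel, 72)
        model = fit_treatment_hazard_model(rt, WeightModelSpec())
        coef = model.coef_table.loc["sofa"]
        assert coef["coef"] > 0
        assert abs(coef["coef"] - 0.3) < 2 * coef["se"]

    def test_duplicated_rows_leave_coefficients_essentially_unchanged(self):
        # the likelihood is weight-equivariant; the fixed stabilizing ridge
        # halves in relative influence when the data are duplicated, so exact
        # equality is relaxed to a tolerance far below any usable effect size
        rt = _flat_risk_table(n_per_hour=1000, rate=0.25, seed=2)
        rt["sofa"] = np.random.default_rng(4).normal(8, 3, len(rt))
        m1 = fit_treatment_hazard_model(rt, WeightModelSpec(), covariates=("sofa",))
        m2 = fit_treatment_hazard_model(
            pd.concat([rt, rt], ignore_index=True), WeightModelSpec(),
            covariates=("sofa",))
        assert np.allclose(m1.params.to_numpy(), m2.params.to_numpy(), atol=2e-3)

    def test_complete_separation_detected(self):
        rt = _flat_risk_table(rate=0.2, seed=3)
        rt["marker"] = rt["initiated"].astype(float)  # perfectly separating
        with pytest.raises(WeightModelError, match="separation"):
            fit_treatment_hazard_model(rt, WeightModelSpec(), covariates=("marker",))

    def test_empty_risk_set_rejected(self):
        rt = _flat_risk_table(rate=0.0)
        with pytest.raises(WeightModelError):
            fit_treatment_hazard_model(rt, WeightModelSpec(), covariates=())

    def test_unpenalized_fit_matches_independent_mle(self):
        """With the ridge switched off the in-package Newton solver agrees
        with an independent logistic MLE (statsmodels GLM) to high precision."""
        import statsmodels.api as sm
        from renalccw.weights import ridge_logistic

        rng = np.random.default_rng(6)
        n = 3000
        X = np.column_stack([np.ones(n), rng.normal(8, 3, n),
                             rng.integers(0, 2, n)])
        y = (rng.random(n) < 1 / (1 + np.exp(-(-3 + 0.2 * X[:, 1]
                                               + 0.5 * X[:, 2])))).astype(float)
        beta, _ = ridge_logistic(X, y, penalty=0.0)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(beta, ref.params, atol=1e-6)


class _StubModel:
    """Hazard model stub returning hand-set probabilities keyed by hour."""

    def __init__(self, by_hour):
        self.by_hour = by_hour

    def predict(self, df):
        return df["hours_since_eligibility"].map(self.by_hour).to_numpy()


class TestStabilizedWeights:
    def test_hand_computed_cumulative_product(self):
        """Two-hour toy with hand-set probabilities: denominator initiation
        probabilities 0.4 then 0.5, numerator 0.5 then 0.5.  The never-arm
        hour-2 weight is the ratio of remain-untreated products,
        (0.5*0.5)/(0.6*0.5) = 0.83333; the early clone treated in hour 2
        carries ((1-0.5)/(1-0.4)) * (0.5/0.5) = 0.83333 as well."""
        eligible = make_eligible_frame([
            {"subject_id": 0, "init_offset": 2.0},   # initiates in hour 2
            {"subject_id": 1},                        # never initiates
        ])
        clones = apply_protocol_censoring(clone_subjects(eligible, 2), 2,
                                          horizon_days=90)
        rt = pd.DataFrame({
            "subject_id": [0, 0, 1, 1],
            "hours_since_eligibility": [1.0, 2.0, 1.0, 2.0],
            "initiated": [0, 1, 0, 0],
        })
        den = _StubModel({1.0: 0.4, 2.0: 0.5})
        num = _StubModel({1.0: 0.5, 2.0: 0.5})
        w = compute_stabilized_ipw(clones, rt, den, num, 2,
                                   truncation_percentiles=(0.0, 100.0))
        pt = w.person_time.set_index(["subject_id", "arm", "hour"])["sw"]
        assert pt[(1, "never", 2.0)] == pytest.approx(0.25 / 0.30)
        assert pt[(1, "never", 1.0)] == pytest.approx(0.5 / 0.6)
        assert pt[(0, "early", 2.0)] == pytest.approx((0.5 / 0.6) * (0.5 / 0.5))
        # never clone of subject 0 is censored at hour 2: weight entering
        assert pt[(0, "never", 2.0)] == pytest.approx(0.5 / 0.6)

    def test_identical_models_give_unit_weights(self):
        eligible = make_eligible_frame(
            [{"subject_id": i, "init_offset": np.nan} for i in range(4)])
        clones = apply_protocol_censoring(clone_subjects(eligible, 3), 3,
                                          horizon_days=90)
        rt = pd.DataFrame({
            "subject_id": np.repeat(np.arange(4), 3),
            "hours_since_eligibility": np.tile([1.0, 2.0, 3.0], 4),
            "initiated": 0,
        })
        m = _StubModel({1.0: 0.2, 2.0: 0.3, 3.0: 0.1})
        w = compute_stabilized_ipw(clones, rt, m, m, 3)
        assert np.allclose(w.person_time["sw"], 1.0)

    def test_degenerate_probability_rejected(self):
        eligible = make_eligible_frame([{"subject_id": 0}])
        clones = apply_protocol_censoring(clone_subjects(eligible, 2), 2)
        rt = pd.DataFrame({"subject_id": [0, 0],
                           "hours_since_eligibility": [1.0, 2.0],
                           "initiated": [0, 0]})
        bad = _StubModel({1.0: 1.0, 2.0: 0.5})
        with pytest.raises(WeightModelError, match="truncate|respecify"):
            compute_stabilized_ipw(clones, rt, bad, bad, 2)

    def test_stabilization_and_truncation_monotonicity(self, midsize_weighted):
        w = midsize_weighted["weighted"]
        assert abs(w.mean_sw - 1.0) < 0.05
        sw = w.person_time["sw"]
        tight = sw.clip(*np.percentile(sw, [5, 95]))
        loose = sw.clip(*np.percentile(sw, [1, 99]))
        assert tight.max() <= loose.max() and tight.min() >= loose.min()


class TestBalanceAndVif:
    def test_identical_arms_smd_zero(self):
        df = pd.DataFrame({
            "arm": ["early"] * 50 + ["never"] * 50,
            "x": list(range(50)) * 2,
        })
        out = smd_balance(df, ["x"])
        assert out["smd"].iloc[0] == pytest.approx(0.0)

    def test_closed_form_unit_smd(self):
        rng = np.random.default_rng(0)
        n = 40_000
        df = pd.DataFrame({
            "arm": ["early"] * n + ["never"] * n,
            "x": np.concatenate([rng.normal(1, 1, n), rng.normal(0, 1, n)]),
        })
        out = smd_balance(df, ["x"])
        assert out["smd"].iloc[0] == pytest.approx(1.0, abs=0.03)

    def test_zero_sd_flagging(self):
        df = pd.DataFrame({"arm": ["early", "early", "never", "never"],
                           "x": [1.0, 1.0, 1.0, 1.0],
                           "y": [1.0, 1.0, 2.0, 2.0]})
        out = smd_balance(df, ["x", "y"])
        assert out.loc[out.covariate == "x", "smd"].iloc[0] == 0.0
        assert out.loc[out.covariate == "y", "undefined"].iloc[0]

    def test_vif_orthogonal_and_collinear(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(0, 1, 5000),
                          "b": rng.normal(0, 1, 5000)})
        out = vif_table(X)
        assert (out["vif"] < 1.1).all()
        X["c"] = X["a"] + rng.normal(0, 0.01, 5000)
        out2 = vif_table(X).set_index("covariate")
        assert out2.loc["c", "vif"] > 5
        X["d"] = 2.0 * X["a"]
        with pytest.warns(UserWarning, match="collinear"):
            out3 = vif_table(X).set_index("covariate")
        assert np.isinf(out3.loc["d", "vif"])

    def test_default_simulator_weight_covariates_have_low_vif(self, midsize_weighted):
        from renalccw.config import WEIGHT_DENOMINATOR_COVARIATES
        el = midsize_weighted["eligible"]
        out = vif_table(el[list(WEIGHT_DENOMINATOR_COVARIATES)])
        assert (out["vif"] < 5).all()
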