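"""Cox screening, risk-score stratification, Kaplan-Meier and log-rank."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from cernet.survival import (
    RiskModel,
    build_risk_model,
    cox_univariate,
    evaluate_signature,
    kaplan_meier,
    logrank_test,
    screen_candidates,
    split_train_test,
    stratify,
)


def clinical_frame(times, events, ids=None):
    ids = ids or [f"p{i}" for i in range(len(times))]
    return pd.DataFrame({"sample_id": ids, "time": times, "event": events})


def cohort_with_effect(n=300, beta=0.8, censor=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    hazards = 0.1 * np.exp(beta * x)
    t = rng.exponential(1 / hazards)
    if censor > 0:
        c = rng.exponential(1 / (censor * 0.1), size=n)
        event = (t <= c).astype(int)
        t = np.minimum(t, c)
    else:
        event = np.ones(n, dtype=int)
    ids = [f"p{i}" for i in range(n)]
    clinical = clinical_frame(t, event, ids)
    expr = pd.Series(x, index=ids, name="GENE")
    return expr, clinical


class TestSplit:
    def test_half_split_of_422_gives_211_and_211(self):
        clinical = clinical_frame(np.arange(1, 423), [1] * 422)
        train, test = split_train_test(clinical, 0.5, seed=1)
        assert len(train) == 211 and len(test) == 211

    def test_partition_properties_and_determinism(self):
        clinical = clinical_frame(np.arange(1, 102), [1] * 101)
        train, test = split_train_test(clinical, 0.5, seed=7)
        assert abs(len(train) - len(test)) <= 1
        assert set(train) | set(test) == set(clinical["sample_id"])
        assert set(train) & set(test) == set()
        again = split_train_test(clinical, 0.5, seed=7)
        assert (train, test) == again
        assert split_train_test(clinical, 0.5, seed=8) != again

    def test_invalid_fraction_rejected(self):
        clinical = clinical_frame([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError):
            split_train_test(clinical, 1.5)


class TestCoxUnivariate:
    def test_hazard_ratio_is_exp_of_coefficient(self):
        expr, clinical = cohort_with_effect(n=120, beta=0.5, seed=3)
        fit = cox_univariate(expr, clinical)
        assert fit.hazard_ratio == pytest.approx(math.exp(fit.coefficient), rel=1e-15)
        assert fit.ci_low <= fit.hazard_ratio <= fit.ci_high

    def test_agrees_with_lifelines_reference(self):
        expr, clinical = cohort_with_effect(n=200, beta=0.6, censor=0.3, seed=5)
        fit = cox_univariate(expr, clinical)
        df = clinical.copy()
        df["x"] = expr.loc[df["sample_id"]].to_numpy()
        ref = CoxPHFitter().fit(df[["time", "event", "x"]], "time", "event")
        assert fit.coefficient == pytest.approx(ref.params_["x"], abs=1e-6)
        assert fit.se == pytest.approx(ref.standard_errors_["x"], abs=1e-6)
        assert fit.p_value == pytest.approx(ref.summary.loc["x", "p"], abs=1e-6)

    def test_breslow_tie_handling_against_reference(self):
        # heavy ties: integer-rounded times
        rng = np.random.default_rng(11)
        x = rng.normal(size=150)
        t = np.ceil(rng.exponential(5 * np.exp(-0.5 * x)))
        clinical = clinical_frame(t, [1] * 150)
        expr = pd.Series(x, index=clinical["sample_id"].to_numpy(), name="g")
        fit = cox_univariate(expr, clinical)
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        y = np.array(
            [(True, ti) for ti in t], dtype=[("event", "?"), ("time", "<f8")]
        )
        ref = CoxPHSurvivalAnalysis(ties="breslow").fit(x.reshape(-1, 1), y)
        assert fit.coefficient == pytest.approx(ref.coef_[0], abs=1e-5)

    def test_null_covariate_gives_near_zero_coefficient(self):
        expr, clinical = cohort_with_effect(n=500, beta=0.0, seed=9)
        fit = cox_univariate(expr, clinical)
        assert abs(fit.coefficient) < 0.15
        assert fit.p_value > 0.001

    def test_recovers_planted_log_hazard(self):
        expr, clinical = cohort_with_effect(n=600, beta=0.7, seed=13)
        fit = cox_univariate(expr, clinical)
        assert fit.coefficient == pytest.approx(0.7, abs=0.15)

    def test_recovery_bias_and_rmse_across_replicates(self):
        errs = []
        for seed in range(40):
            expr, clinical = cohort_with_effect(n=600, beta=0.7, seed=100 + seed)
            errs.append(cox_univariate(expr, clinical).coefficient - 0.7)
        errs = np.array(errs)
        assert abs(errs.mean()) < 0.05
        assert np.sqrt((errs**2).mean()) < 0.15

    def test_monotone_likelihood_flagged_unreliable(self):
        # perfectly separating covariate drives beta to infinity
        clinical = clinical_frame(np.arange(1, 21), [1] * 20)
        expr = pd.Series(np.arange(20, 0, -1), index=clinical["sample_id"].to_numpy(), dtype=float)
        fit = cox_univariate(expr, clinical)
        assert not fit.converged

    def test_preconditions_enforced(self):
        clinical = clinical_frame([1, 2, 3], [1, 1, 1])
        expr = pd.Series([1.0, 2.0, 3.0], index=clinical["sample_id"].to_numpy())
        with pytest.raises(ValueError):
            cox_univariate(expr, clinical)


class TestRiskModel:
    def expression(self, ids):
        rng = np.random.default_rng(17)
        return pd.DataFrame(
            rng.normal(size=(3, len(ids))), index=["g1", "g2", "g3"], columns=ids
        )

    def test_single_gene_unit_weight_score_is_expression(self):
        ids = [f"p{i}" for i in range(10)]
        expr = self.expression(ids)
        model = RiskModel(("g1",), (1.0,), cutoff=0.0)
        np.testing.assert_allclose(model.scores(expr, ids), expr.loc["g1"])

    def test_zero_coefficients_give_zero_scores_and_cutoff(self):
        ids = [f"p{i}" for i in range(10)]
        expr = self.expression(ids)
        fits = pd.DataFrame({"gene_id": ["g1", "g2"], "coefficient": [0.0, 0.0]})
        model = build_risk_model(fits, expr, ids)
        assert model.cutoff == 0.0
        assert (model.scores(expr, ids) == 0).all()

    def test_matrix_product_equals_per_patient_loop(self):
        ids = [f"p{i}" for i in range(8)]
        expr = self.expression(ids)
        model = RiskModel(("g1", "g2", "g3"), (0.5, -1.2, 2.0), cutoff=0.0)
        scores = model.scores(expr, ids)
        for pid in ids:
            manual = sum(
                c * expr.loc[g, pid] for g, c in zip(model.genes, model.coefficients)
            )
            assert scores[pid] == pytest.approx(manual, abs=1e-12)

    def test_median_split_on_training_cohort(self):
        ids = [f"p{i}" for i in range(11)]
        expr = self.expression(ids)
        fits = pd.DataFrame({"gene_id": ["g1"], "coefficient": [1.0]})
        model = build_risk_model(fits, expr, ids)
        labels = stratify(model, expr, ids)
        assert (labels == "high").sum() == 5  # median patient goes low
        assert (labels == "low").sum() == 6

    def test_missing_gene_is_hard_error(self):
        ids = [f"p{i}" for i in range(5)]
        expr = self.expression(ids)
        model = RiskModel(("ghost",), (1.0,), cutoff=0.0)
        with pytest.raises(ValueError, match="ghost"):
            model.scores(expr, ids)

    def test_all_scores_below_cutoff_all_low(self):
        ids = [f"p{i}" for i in range(5)]
        expr = self.expression(ids)
        model = RiskModel(("g1",), (1.0,), cutoff=1e9)
        assert (stratify(model, expr, ids) == "low").all()


class TestKaplanMeier:
    def test_all_censored_curve_is_constant_one(self):
        curve = kaplan_meier(clinical_frame([2, 3, 5], [0, 0, 0]))
        assert (curve["survival"] == 1).all()

    def test_single_patient_single_step(self):
        curve = kaplan_meier(clinical_frame([5], [1])).set_index("time")
        assert curve.loc[0, "survival"] == 1
        assert curve.loc[5, "survival"] == 0

    def test_hand_product_limit_with_censoring(self):
        # times 1(event), 2(censored), 3(event): S(1)=2/3, S(3)=0
        curve = kaplan_meier(clinical_frame([1, 2, 3], [1, 0, 1])).set_index("time")
        assert curve.loc[1, "survival"] == pytest.approx(2 / 3)
        assert curve.loc[3, "survival"] == pytest.approx(0.0)

    def test_equals_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(5, size=40)
        curve = kaplan_meier(clinical_frame(times, [1] * 40))
        for t, s, _ in curve.itertuples(index=False):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_drops_only_at_event_times(self):
        curve = kaplan_meier(clinical_frame([1, 2, 3, 4], [1, 0, 0, 1]))
        drops = curve["time"][curve["survival"].diff() < 0]
        assert set(drops) == {1.0, 4.0}


class TestLogrank:
    def test_identical_groups_give_zero_chi_square(self):
        g = clinical_frame([1, 2, 3, 4], [1, 1, 0, 1])
        chi2, p = logrank_test(g, g.assign(sample_id=list("wxyz")))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        a = clinical_frame(rng.exponential(5, 30), rng.integers(0, 2, 30))
        b = clinical_frame(rng.exponential(8, 25), rng.integers(0, 2, 25), ids=[f"q{i}" for i in range(25)])
        assert logrank_test(a, b) == pytest.approx(logrank_test(b, a))

    def test_zero_events_flagged_undefined(self):
        a = clinical_frame([1, 2], [0, 0])
        b = clinical_frame([3, 4], [0, 0], ids=["x", "y"])
        chi2, p = logrank_test(a, b)
        assert math.isnan(chi2) and math.isnan(p)

    def test_strong_planted_effect_detected(self, rng):
        a = clinical_frame(rng.exponential(2, 100), [1] * 100)
        b = clinical_frame(rng.exponential(8, 100), [1] * 100, ids=[f"q{i}" for i in range(100)])
        chi2, p = logrank_test(a, b)
        assert p < 1e-6


class TestEvaluateSignature:
    def planted_cohort(self, n=400, beta=0.9, seed=2):
        rng = np.random.default_rng(seed)
        ids = [f"p{i}" for i in range(n)]
        expr = pd.DataFrame(
            rng.normal(size=(3, n)), index=["risk", "null1", "null2"], columns=ids
        )
        hazards = 0.1 * np.exp(beta * expr.loc["risk"].to_numpy())
        t = rng.exponential(1 / hazards)
        clinical = clinical_frame(t, [1] * n, ids)
        return expr, clinical

    def test_planted_risk_gene_stratifies_train_and_test(self):
        expr, clinical = self.planted_cohort()
        out = evaluate_signature(["risk", "null1", "null2"], expr, clinical, seed=4)
        report = out["report"].set_index("cohort")
        assert report.loc["train", "p_value"] < 0.05
        assert report.loc["test", "p_value"] < 0.05
        assert "risk" in out["model"].genes

    def test_null_cohort_reports_nonsignificant_split(self):
        expr, clinical = self.planted_cohort(beta=0.0, seed=6)
        out = evaluate_signature(["risk", "null1"], expr, clinical, seed=4)
        report = out["report"].set_index("cohort")
        # held-out test should not systematically separate under the null
        assert report.loc["test", "p_value"] > 0.001

    def test_external_cohort_uses_training_cutoff(self):
        expr, clinical = self.planted_cohort(seed=8)
        ext_expr, ext_clin = self.planted_cohort(n=200, seed=9)
        out = evaluate_signature(
            ["risk"], expr, clinical, seed=4, external=(ext_expr, ext_clin)
        )
        report = out["report"].set_index("cohort")
        assert report.loc["external", "p_value"] < 0.05
        assert report.loc["external", ["n_high", "n_low"]].sum() == 200
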