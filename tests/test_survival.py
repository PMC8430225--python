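"""Cox partial likelihood, risk scores, Kaplan-Meier and log-rank."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from scipy.optimize import minimize_scalar

import lncnet as L
from lncnet.errors import DegenerateDataError, ValidationError
from lncnet.simulate import simulate_expression, simulate_survival
from lncnet.survival import cox_partial_loglik


class TestCoxUnivariate:
    def test_symmetric_groups_give_zero_beta(self):
        # two groups with identical (time, event) patterns
        time = np.array([1.0, 2, 3, 1, 2, 3])
        event = np.array([1.0, 1, 0, 1, 1, 0])
        x = np.array([0.0, 0, 0, 1, 1, 1])
        fit = L.cox_univariate(x, time, event)
        assert abs(fit.beta) < 1e-6
        assert fit.hr == pytest.approx(np.exp(fit.beta))

    def test_matches_bounded_likelihood_maximisation(self):
        # 6-patient toy with interleaved deaths (finite maximiser); the
        # oracle maximises the same Breslow partial likelihood by bounded
        # scalar search, independent of the Newton-Raphson path
        x = np.array([0.0, 1, 0, 1, 0, 1])
        time = np.arange(1.0, 7.0)
        event = np.ones(6)
        fit = L.cox_univariate(x, time, event)
        oracle = minimize_scalar(lambda b: -cox_partial_loglik(b, x, time, event),
                                 bounds=(-10, 10), method="bounded",
                                 options={"xatol": 1e-10})
        assert fit.beta == pytest.approx(oracle.x, abs=1e-4)
        assert fit.converged

    def test_planted_beta_recovered_within_3_se(self):
        expr, _ = simulate_expression(["G1"], n_samples=1000, seed=3)
        clinical, _ = simulate_survival(expr, {"G1": 0.5}, seed=4)
        fit = L.cox_univariate(expr.loc["G1"].values, clinical["time"].values,
                               clinical["event"].values)
        assert abs(fit.beta - 0.5) <= 3 * fit.se

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(9)
        n = 300
        x = rng.standard_normal(n)
        expr = pd.DataFrame(x[None, :], index=["G"],
                            columns=[f"S{i}" for i in range(n)])
        clinical, _ = simulate_survival(expr, {"G": 0.4}, seed=10)
        fit = L.cox_univariate(x, clinical["time"].values, clinical["event"].values)
        df = pd.DataFrame({"x": x, "T": clinical["time"].values,
                           "E": clinical["event"].values})
        ref = CoxPHFitter().fit(df, "T", "E")
        assert fit.beta == pytest.approx(ref.params_["x"], abs=1e-4)
        assert fit.se == pytest.approx(ref.standard_errors_["x"], abs=1e-4)

    def test_separated_groups_blow_up(self):
        # complete separation: the partial likelihood is monotone in beta
        x = np.array([1.0, 1, 1, 0, 0, 0])
        fit = L.cox_univariate(x, np.arange(1.0, 7.0), np.ones(6))
        assert fit.beta > 5

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            L.cox_univariate(np.ones(5), np.arange(5.0), np.ones(5))
        with pytest.raises(DegenerateDataError):
            L.cox_univariate(np.arange(5.0), np.arange(5.0), np.zeros(5))


class TestRiskScore:
    def test_zero_coefficients(self):
        expr = pd.DataFrame([[1.0, 2], [3, 4]], index=["a", "b"],
                            columns=["s1", "s2"])
        model = L.RiskModel(gene_ids=["a", "b"], coefs=[0.0, 0.0])
        assert (L.risk_score(expr, model) == 0).all()

    def test_single_gene_identity(self):
        expr = pd.DataFrame([[2.5]], index=["a"], columns=["s1"])
        model = L.RiskModel(gene_ids=["a"], coefs=[1.0])
        assert L.risk_score(expr, model)["s1"] == pytest.approx(2.5)

    def test_linear_combination(self):
        expr = pd.DataFrame([[2.0], [1.0]], index=["a", "b"], columns=["s1"])
        model = L.RiskModel(gene_ids=["a", "b"], coefs=[0.5, -1.0])
        assert L.risk_score(expr, model)["s1"] == pytest.approx(0.0)

    def test_missing_gene_listed(self):
        expr = pd.DataFrame([[1.0]], index=["a"], columns=["s1"])
        model = L.RiskModel(gene_ids=["a", "zz"], coefs=[1.0, 1.0])
        with pytest.raises(ValidationError, match="zz"):
            L.risk_score(expr, model)


class TestStratifyByMean:
    def test_boundary_value_goes_low(self):
        labels = L.stratify_by_mean(pd.Series([1.0, 2.0, 3.0]))
        assert list(labels) == ["low", "low", "high"]

    def test_constant_values_all_low(self):
        labels = L.stratify_by_mean(pd.Series([2.0, 2.0, 2.0]))
        assert (labels == "low").all()

    def test_symmetric_values_balanced(self):
        labels = L.stratify_by_mean(pd.Series([-2.0, -1.0, 1.0, 2.0]))
        assert (labels == "high").sum() == 2


class TestKMLogrank:
    def test_identical_groups_null(self):
        time = np.array([1.0, 2, 3, 1, 2, 3])
        event = np.array([1.0, 1, 0, 1, 1, 0])
        groups = ["high"] * 3 + ["low"] * 3
        cmp_ = L.km_logrank(groups, time, event)
        assert cmp_.chi2 == pytest.approx(0.0, abs=1e-12)
        assert cmp_.p == pytest.approx(1.0)
        assert cmp_.hr == pytest.approx(1.0)

    def test_hand_tabulated_o_e_v(self):
        # at t=1 both group-"high" members die (d=2, n=5, n1=2):
        # E1 = 2*(2/5), V = 2*(2/5)(3/5)(5-2)/(5-1); later event times have
        # no "high" members at risk so they add nothing to E1 or V
        time = np.array([1.0, 1.0, 4.0, 5.0, 6.0])
        event = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        groups = ["high", "high", "low", "low", "low"]
        cmp_ = L.km_logrank(groups, time, event)
        e1 = 2 * 2 / 5
        v = 2 * (2 / 5) * (3 / 5) * (5 - 2) / (5 - 1)
        # remaining event times involve only group "low" members: each
        # contributes E1 = 0 and V = 0 (n1 = 0)
        assert cmp_.o1 == 2 and cmp_.e1 == pytest.approx(e1, abs=1e-10)
        assert cmp_.chi2 == pytest.approx((2 - e1) ** 2 / v, abs=1e-10)

    def test_km_equals_empirical_survival_without_censoring(self):
        time = np.array([3.0, 1.0, 2.0, 5.0, 4.0])
        curve = L.km_curve(time, np.ones(5))
        for k, t in enumerate(sorted(time), start=1):
            row = curve[curve.time == t].iloc[0]
            assert row.survival == pytest.approx((5 - k) / 5)

    def test_km_curves_monotone_from_one(self):
        rng = np.random.default_rng(2)
        curve = L.km_curve(rng.exponential(5, 100), rng.integers(0, 2, 100))
        assert curve.survival.iloc[0] == 1.0
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert ((curve.survival >= 0) & (curve.survival <= 1)).all()

    def test_label_swap_inverts_hr_keeps_chi2(self):
        rng = np.random.default_rng(4)
        time = rng.exponential(10, 80)
        event = np.ones(80)
        groups = np.where(rng.random(80) < 0.5, "high", "low")
        a = L.km_logrank(groups, time, event)
        swapped = np.where(groups == "high", "low", "high")
        b = L.km_logrank(swapped, time, event)
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-10)
        assert a.hr == pytest.approx(1 / b.hr, rel=1e-10)

    def test_agrees_with_lifelines_logrank(self):
        rng = np.random.default_rng(6)
        time = rng.exponential(10, 120)
        event = (rng.random(120) < 0.7).astype(float)
        groups = np.where(rng.random(120) < 0.5, "high", "low")
        mine = L.km_logrank(groups, time, event)
        ref = logrank_test(time[groups == "high"], time[groups == "low"],
                           event[groups == "high"], event[groups == "low"])
        assert mine.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_zero_event_group_hr_not_estimable(self):
        time = np.array([1.0, 2, 3, 4.0, 5, 6])
        event = np.array([1.0, 1, 1, 0.0, 0, 0])
        groups = ["high"] * 3 + ["low"] * 3
        cmp_ = L.km_logrank(groups, time, event)
        assert np.isnan(cmp_.hr)
        assert cmp_.chi2 > 0

    def test_needs_exactly_two_groups(self):
        with pytest.raises(ValidationError):
            L.km_logrank(["a"] * 4, np.arange(4.0), np.ones(4))


class TestEndToEndRecovery:
    def test_risk_model_pipeline_detects_planted_hazard(self):
        # per-gene Cox -> risk score -> mean split -> log-rank on data with
        # a planted hazard signal detects it in >= 95% of replicates
        genes = [f"G{i}" for i in range(5)]
        coefs = {g: 0.3 for g in genes}
        detected = 0
        reps = 200
        for rep in range(reps):
            expr, _ = simulate_expression(genes, n_samples=400, seed=1000 + rep)
            clinical, _ = simulate_survival(expr, coefs, seed=2000 + rep)
            model, _ = L.RiskModel.from_univariate_cox(expr, clinical, genes)
            scores = L.risk_score(expr, model)
            labels = L.stratify_by_mean(scores)
            cmp_ = L.km_logrank(labels, clinical["time"].values,
                                clinical["event"].values)
            detected += cmp_.p < 0.05
        assert detected / reps >= 0.95
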