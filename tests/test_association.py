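"""Logistic and linear association fits, interaction test, concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import factorgrs as fg
from factorgrs.association import RankDeficiencyError, SeparationError


def table_2x2(cases_exp, ctrl_exp, cases_unexp, ctrl_unexp):
    y = np.concatenate(
        [
            np.ones(cases_exp), np.zeros(ctrl_exp),
            np.ones(cases_unexp), np.zeros(ctrl_unexp),
        ]
    )
    x = np.concatenate(
        [np.ones(cases_exp + ctrl_exp), np.zeros(cases_unexp + ctrl_unexp)]
    )
    return y, pd.DataFrame({"exposed": x})


class TestFitLogistic:
    def test_saturated_design_reproduces_cross_product_or(self):
        y, X = table_2x2(10, 80, 20, 90)
        res = fg.fit_logistic(y, X)
        assert np.exp(res["estimate"].iloc[0]) == pytest.approx(0.5625, abs=1e-8)
        assert res["n"].iloc[0] == 200

    def test_constant_covariate_raises_not_drops(self):
        y, X = table_2x2(10, 80, 20, 90)
        X["flat"] = 1.0
        with pytest.raises(RankDeficiencyError, match="flat"):
            fg.fit_logistic(y, X)

    def test_separated_outcome_raises(self):
        y = np.array([0, 0, 0, 1, 1, 1], float)
        X = pd.DataFrame({"x": [-2.0, -1.5, -1.0, 1.0, 1.5, 2.0]})
        with pytest.raises(SeparationError):
            fg.fit_logistic(y, X)

    def test_non_binary_outcome_rejected(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="binary"):
            fg.fit_logistic(np.array([0.0, 0.5, 1.0]), X)

    def test_wald_type_one_error_calibrated(self):
        # null predictor: rejection rate at alpha=0.05 should be ~5%
        rng = np.random.default_rng(2026)
        n, reps, rejections = 5000, 200, 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rng.binomial(1, 0.3, n).astype(float)
            res = fg.fit_logistic(y, pd.DataFrame({"x": x}))
            rejections += res["p"].iloc[0] < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_frequency_weights_equal_row_duplication(self):
        y, X = table_2x2(3, 5, 4, 6)
        w = np.full(len(y), 3.0)
        dup = fg.fit_logistic(np.repeat(y, 3), pd.DataFrame({"exposed": np.repeat(X["exposed"], 3)}))
        wtd = fg.fit_logistic(y, X, weights=w, weight_kind="frequency")
        assert wtd["estimate"].iloc[0] == pytest.approx(dup["estimate"].iloc[0], abs=1e-9)
        assert wtd["se"].iloc[0] == pytest.approx(dup["se"].iloc[0], rel=1e-6)


class TestFitLinear:
    def test_parameter_recovery(self, rng):
        n = 10_000
        g = rng.integers(0, 2, n).astype(float)
        y = 2.0 * g + rng.normal(0, 0.1, n)
        res = fg.fit_linear(y, pd.DataFrame({"g": g}))
        assert abs(res["estimate"].iloc[0] - 2.0) < 2 * res["se"].iloc[0]

    def test_equal_weights_match_unweighted(self, rng):
        n = 300
        X = pd.DataFrame({"x": rng.standard_normal(n)})
        y = 1.0 + 0.5 * X["x"] + rng.standard_normal(n)
        base = fg.fit_linear(y, X)
        wtd = fg.fit_linear(y, X, weights=np.full(n, 2.0), weight_kind="frequency")
        assert abs(wtd["estimate"].iloc[0] - base["estimate"].iloc[0]) < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        n, p = 40, 3
        X = pd.DataFrame(rng.standard_normal((n, p)), columns=list("abc"))
        y = rng.standard_normal(n)
        res = fg.fit_linear(y, X)
        M = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.solve(M.T @ M, M.T @ y)
        for j, term in enumerate(list("abc"), start=1):
            assert abs(res.set_index("term").loc[term, "estimate"] - beta[j]) < 1e-10

    def test_missing_outcome_rows_dropped(self, rng):
        y = rng.standard_normal(50)
        y[:5] = np.nan
        res = fg.fit_linear(y, pd.DataFrame({"x": rng.standard_normal(50)}))
        assert res["n"].iloc[0] == 45

    def test_probability_weights_recover_population_effect(self):
        # stratum-heterogeneous effect + oversampled stratum: the weighted
        # fit targets the population-average slope, the unweighted one is
        # pulled toward the oversampled stratum
        rng = np.random.default_rng(5)
        n = 30_000
        stratum = rng.binomial(1, 0.5, n)  # population: 50/50
        x = rng.standard_normal(n)
        slope = np.where(stratum == 1, 0.8, 0.2)
        y = slope * x + rng.standard_normal(n) * 0.5
        keep = np.ones(n, bool)
        # sample: stratum 1 over-represented 3:1
        copies = np.where(stratum == 1, 3, 1)
        idx = np.repeat(np.arange(n), copies)
        w = 1.0 / copies[idx]
        res_w = fg.fit_linear(y[idx], pd.DataFrame({"x": x[idx]}), weights=w)
        res_u = fg.fit_linear(y[idx], pd.DataFrame({"x": x[idx]}))
        pop = 0.5  # average of 0.8 and 0.2
        assert abs(res_w.set_index("term").loc["x", "estimate"] - pop) < 0.02
        assert res_u.set_index("term").loc["x", "estimate"] > 0.6


class TestInteraction:
    def test_recovers_true_product_effect(self, rng):
        n = 10_000
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        y = 0.3 * a + 0.4 * b + 0.2 * a * b + rng.standard_normal(n)
        res = fg.interaction_test(y, a, b)
        assert res["term"].iloc[0] == "score_a:score_b"
        assert abs(res["estimate"].iloc[0] - 0.2) < 2 * res["se"].iloc[0]

    def test_degenerate_constant_score_raises(self, rng):
        n = 100
        a = rng.standard_normal(n)
        b = np.ones(n)
        y = rng.standard_normal(n)
        with pytest.raises(RankDeficiencyError):
            fg.interaction_test(y, a, b)

    def test_additive_truth_gives_null_product_term(self, rng):
        n = 5000
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        y = 0.5 * a - 0.3 * b + rng.standard_normal(n)
        res = fg.interaction_test(y, a, b)
        assert res["p"].iloc[0] > 0.001


class TestEffectConcordance:
    def make_results(self, est, ids=None):
        ids = ids or [f"m{i}" for i in range(len(est))]
        return pd.DataFrame(
            {"outcome_id": ids, "estimate": est, "se": 0.1, "term": "g", "p": 0.5,
             "n": 100, "cohort_id": "c"}
        )

    def test_self_concordance(self):
        a = self.make_results([0.1, -0.2, 0.3, 0.05])
        out = fg.effect_concordance(a, a)
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(1.0)

    def test_affine_case(self):
        b = self.make_results([0.1, -0.2, 0.3, 0.05])
        a = self.make_results([0.2, -0.4, 0.6, 0.10])
        out = fg.effect_concordance(a, b)
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0)

    def test_independent_effects_have_low_r2(self):
        rng = np.random.default_rng(99)
        low = 0
        for _ in range(100):
            a = self.make_results(rng.standard_normal(145))
            b = self.make_results(rng.standard_normal(145))
            low += fg.effect_concordance(a, b)["r_squared"] < 0.1
        assert low >= 95

    def test_too_few_shared_outcomes_raise(self):
        a = self.make_results([0.1, 0.2], ids=["x", "y"])
        with pytest.raises(ValueError, match="3"):
            fg.effect_concordance(a, a)


def test_or_ci_derivable_from_result_exactly():
    y, X = table_2x2(10, 80, 20, 90)
    res = fg.fit_logistic(y, X)
    row = res.iloc[0]
    s = fg.or_from_logistic(row)
    assert s.odds_ratio == pytest.approx(np.exp(row["estimate"]))
    assert s.ci_low == pytest.approx(np.exp(row["estimate"] - 1.959964 * row["se"]), rel=1e-6)
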