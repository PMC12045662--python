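"""Agreement, correlation, BMI classes, gap tables, group tests, stepwise."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import heartage as ha
from heartage.stats import BMI_CLASSES, classify_bmi, stepwise_ols


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.array([20.0, 40.0, 60.0])
        res = ha.bland_altman(x, x, mode="absolute")
        assert res.bias == 0.0
        assert res.lower_loa == res.upper_loa == 0.0
        assert res.p_value == 1.0

    def test_constant_offset(self):
        chrono = np.linspace(20, 70, 25)
        res = ha.bland_altman(chrono + 4.6, chrono, mode="absolute")
        assert res.bias == pytest.approx(4.6)
        assert res.upper_loa - res.lower_loa == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_loa(self):
        chrono = np.array([50.0, 50.0, 50.0])
        pred = chrono + np.array([-2.0, 0.0, 2.0])
        res = ha.bland_altman(pred, chrono, mode="absolute")
        assert res.bias == pytest.approx(0.0)
        assert res.upper_loa == pytest.approx(1.96 * 2.0)
        assert res.lower_loa == pytest.approx(-1.96 * 2.0)

    def test_absolute_bias_is_mean_difference(self, rng):
        pred = rng.uniform(20, 90, 100)
        chrono = rng.uniform(20, 90, 100)
        res = ha.bland_altman(pred, chrono, mode="absolute")
        assert res.bias == pytest.approx(pred.mean() - chrono.mean(), abs=1e-12)

    def test_percent_mode_denominator_guard(self):
        with pytest.raises(ValueError):
            ha.bland_altman(np.array([1.0, -5.0]), np.array([1.0, 2.0]),
                            mode="percent")

    def test_minimum_pairs(self):
        with pytest.raises(ValueError):
            ha.bland_altman(np.array([1.0]), np.array([1.0]))


class TestSpearmanCi:
    def test_monotone_transform_perfect(self, rng):
        x = rng.uniform(0, 10, 50)
        res = ha.spearman_ci(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)
        assert res.ci == (1.0, 1.0)

    def test_anti_monotone(self, rng):
        x = rng.uniform(0, 10, 50)
        assert ha.spearman_ci(x, -x**3).rho == pytest.approx(-1.0)

    def test_null_covers_zero(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        res = ha.spearman_ci(x, y)
        assert abs(res.rho) < 0.1
        assert res.ci[0] < 0.0 < res.ci[1]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = ha.spearman_ci(x, y)
        trans = ha.spearman_ci(np.exp(x), y**3)
        assert trans.rho == pytest.approx(base.rho, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            ha.spearman_ci(np.ones(10), np.arange(10.0))


class TestBmiClasses:
    @pytest.mark.parametrize(
        "bmi,label",
        [(24.0, "normal"), (24.999, "normal"), (25.0, "overweight"),
         (29.9, "overweight"), (30.0, "obesity I"), (32.0, "obesity I"),
         (35.0, "obesity II"), (40.0, "obesity III"), (55.0, "obesity III")],
    )
    def test_boundaries(self, bmi, label):
        assert classify_bmi(bmi) == label

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0.1, 80.0))
    def test_partition(self, bmi):
        assert classify_bmi(bmi) in BMI_CLASSES

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_bmi(0.0)


class TestAgeGap:
    def test_zero_gap_everywhere(self, rng):
        n = 60
        cohort = pd.DataFrame(
            {"age_yr": rng.uniform(20, 80, n), "bmi": rng.uniform(18, 45, n)}
        )
        table = ha.age_gap_by_group(cohort, cohort["age_yr"].to_numpy(),
                                    "bmi_class")
        assert np.allclose(table["mean_gap_yr"], 0.0)
        assert np.allclose(table["p_value"].dropna(), 1.0)

    def test_obesity_iii_strongly_positive(self, rng):
        # obesity-III volumetry scores far above any adult chronological age
        n = 40
        pred = ha.predict_heart_age(54.0, 49.0).functional_age
        assert pred == pytest.approx(87.9207 + 0.05241 * 54 + 20, abs=1e-9)
        cohort = pd.DataFrame(
            {"age_yr": rng.uniform(30, 70, n), "bmi": np.full(n, 42.0)}
        )
        table = ha.age_gap_by_group(cohort, np.full(n, pred), "bmi_class")
        row = table[table["group"] == "obesity III"].iloc[0]
        assert row["mean_gap_yr"] > 30

    def test_comorbidity_grouping_adds_between_test(self, rng):
        n = 100
        cohort = pd.DataFrame(
            {
                "age_yr": rng.uniform(20, 80, n),
                "hypertension": np.arange(n) % 2 == 0,
            }
        )
        gaps = rng.normal(0, 3, n)
        table = ha.age_gap_by_group(
            cohort, cohort["age_yr"].to_numpy() + gaps, "hypertension"
        )
        assert "p_between" in table.columns
        assert table["p_between"].iloc[0] > 0.001  # same distribution

    def test_null_independent_t_uniform(self):
        # under identical gap distributions the between-group p is ~U(0,1)
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(200):
            cohort = pd.DataFrame(
                {"age_yr": np.full(400, 50.0),
                 "diabetes": np.arange(400) < 200}
            )
            fage = 50.0 + rng.normal(0, 5, 400)
            t = ha.age_gap_by_group(cohort, fage, "diabetes")
            pvals.append(t["p_between"].iloc[0])
        assert 0.02 < np.mean(np.array(pvals) < 0.25) < 0.45  # ~0.25


class TestCompareGroups:
    def test_identical_groups(self):
        g = {"a": np.arange(30.0), "b": np.arange(30.0)}
        res = ha.compare_groups(g)
        assert res.p_value == pytest.approx(1.0, abs=0.05)
        assert res.posthoc is None

    def test_two_shifted_groups(self, rng):
        res = ha.compare_groups(
            {"a": rng.normal(0, 1, 50), "b": rng.normal(10, 1, 50)}
        )
        assert res.test == "mann-whitney"
        assert res.p_value < 0.001

    def test_three_groups_posthoc_flags_shifted_pairs(self, rng):
        res = ha.compare_groups(
            {
                "a": rng.normal(0, 1, 40),
                "b": rng.normal(0, 1, 40),
                "c": rng.normal(8, 1, 40),
            }
        )
        assert res.test == "kruskal-wallis" and res.p_value < 0.05
        assert res.posthoc[("a", "c")] < 0.01
        assert res.posthoc[("b", "c")] < 0.01
        assert res.posthoc[("a", "b")] > 0.05

    def test_summary_format(self):
        res = ha.compare_groups({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        assert res.summary["a"] == "2 (1.5-2.5)"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ha.compare_groups({"a": [1.0], "b": []})


class TestStepwise:
    def _cohort(self, rng, noise):
        n = 300
        frame = pd.DataFrame(
            {f"x{i}": rng.normal(size=n) for i in range(6)}
        )
        frame["y"] = (
            2.0 * frame["x1"] - 1.5 * frame["x4"] + rng.normal(0, noise, n)
        )
        return frame

    def test_exact_selection_no_noise(self, rng):
        frame = self._cohort(rng, noise=1e-12)
        res = stepwise_ols(frame, "y", [f"x{i}" for i in range(6)])
        assert sorted(res["selected"]) == ["x1", "x4"]
        assert res["coefficients"]["x1"] == pytest.approx(2.0, abs=1e-6)

    def test_noisy_selection_consistency(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(25):
            frame = self._cohort(rng, noise=1.0)
            res = stepwise_ols(frame, "y", [f"x{i}" for i in range(6)])
            hits += set(res["selected"]) >= {"x1", "x4"}
        assert hits >= 24  # true predictors recovered essentially always

    def test_all_noise_false_selection_rate(self):
        rng = np.random.default_rng(4)
        n_selected = 0
        reps = 60
        for _ in range(reps):
            frame = pd.DataFrame({f"x{i}": rng.normal(size=120) for i in range(4)})
            frame["y"] = rng.normal(size=120)
            res = stepwise_ols(frame, "y", [f"x{i}" for i in range(4)])
            n_selected += len(res["selected"])
        rate = n_selected / (reps * 4)
        assert rate < 0.12  # close to the 0.05 entry alpha

    def test_no_candidate_passes_screen(self, rng):
        frame = pd.DataFrame({"x0": rng.normal(size=100)})
        frame["y"] = rng.normal(size=100)
        res = stepwise_ols(frame, "y", ["x0"])
        assert res["selected"] == [] and res["coefficients"] == {}
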