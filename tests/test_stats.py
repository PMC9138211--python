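import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oneway_f_by_hand, rm_anova_f_by_hand
from pris.errors import DegenerateDesignError, ValidationError
from pris.stats import (
    PowerSpec,
    component_regression,
    monte_carlo_power_pearson,
    oneway_anova_posthoc,
    power_pearson,
    rm_anova,
    sample_size_pearson,
    simple_regression,
)


class TestPower:
    def test_planning_sample_size(self):
        """A medium correlation (r = 0.3) needs 85 patients for 80% power."""
        assert sample_size_pearson(PowerSpec(r=0.3, alpha=0.05, power=0.80)) == 85

    def test_sample_size_monotone_in_effect(self):
        n_small = sample_size_pearson(PowerSpec(r=0.2))
        n_large = sample_size_pearson(PowerSpec(r=0.5))
        assert n_small > sample_size_pearson(PowerSpec(r=0.3)) > n_large

    @pytest.mark.parametrize("r", [0.2, 0.3, 0.5])
    def test_sample_size_power_consistency(self, r):
        spec = PowerSpec(r=r)
        n = sample_size_pearson(spec)
        assert power_pearson(n, r, spec.alpha) >= spec.power
        assert power_pearson(n - 1, r, spec.alpha) < spec.power

    def test_power_at_planned_size(self):
        assert power_pearson(85, 0.3, 0.05) == pytest.approx(0.80, abs=0.005)

    def test_null_power_equals_level(self):
        assert power_pearson(100, 0.0, 0.05) == pytest.approx(0.05, abs=1e-9)

    def test_power_tends_to_one(self):
        assert power_pearson(5000, 0.3, 0.05) > 0.999

    @pytest.mark.parametrize(
        "n, r", [(30, 0.0), (30, 0.5), (85, 0.3), (200, 0.3)]
    )
    def test_monte_carlo_agrees_with_analytic(self, n, r):
        """Simulation-based power matches the Fisher z approximation."""
        reps = 5000
        rng = np.random.default_rng(10 * n + int(10 * r))
        emp = monte_carlo_power_pearson(n, r, 0.05, n_reps=reps, rng=rng)
        ana = power_pearson(n, r, 0.05) if r > 0 else 0.05
        se = math.sqrt(max(ana * (1 - ana), 0.002)) / math.sqrt(reps)
        assert abs(emp - ana) <= 3 * se + 0.01

    def test_sample_size_cross_checked_by_simulation(self):
        spec = PowerSpec(r=0.5)
        n = sample_size_pearson(spec)
        rng = np.random.default_rng(42)
        emp = monte_carlo_power_pearson(n, 0.5, 0.05, n_reps=20_000, rng=rng)
        se = math.sqrt(0.8 * 0.2 / 20_000)
        assert emp >= spec.power - 3 * se

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            PowerSpec(r=0.0)
        with pytest.raises(ValidationError):
            power_pearson(3, 0.3)


class TestSimpleRegression:
    def test_perfect_fit(self):
        x = np.arange(1.0, 9.0)
        res = simple_regression(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_toy_set_matches_normal_equations(self):
        """{(1,1),(2,3),(3,2),(4,5),(5,4)}: slope 0.8, intercept 0.6, r 0.8."""
        res = simple_regression([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert res.slope == pytest.approx(0.8)
        assert res.intercept == pytest.approx(0.6)
        assert res.r == pytest.approx(0.8)
        assert res.df == (1, 3)
        assert res.f_stat == pytest.approx(0.64 / 0.36 * 3)

    def test_independent_noise_gives_small_r(self):
        rng = np.random.default_rng(3)
        res = simple_regression(rng.normal(size=2000), rng.normal(size=2000))
        assert res.r < 0.08

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateDesignError):
            simple_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_f_equals_r2_identity(self, seed):
        """F = R^2/(1-R^2) * (n-2) holds exactly for any data."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        res = simple_regression(x, y)
        expected = res.r**2 / (1 - res.r**2) * (n - 2)
        assert res.f_stat == pytest.approx(expected, rel=1e-10)


class TestComponentRegression:
    @staticmethod
    def frame_with_effect(effect, n=400, seed=0):
        rng = np.random.default_rng(seed)
        scores = rng.choice([4, 8, 12], size=n)
        delta = 40.0 + effect * (scores == 12) + rng.normal(0, 10, size=n)
        return pd.DataFrame({"ratio_score": scores, "delta24_pct": delta})

    def test_null_effect_beta_near_zero(self):
        frame = self.frame_with_effect(0.0, seed=1)
        res = component_regression(frame, parameters=["ratio_score"])["ratio_score"]
        betas = res.component_betas
        top = betas.loc[betas["score"] == 12].iloc[0]
        assert top["ci_low"] <= 0.0 <= top["ci_high"]

    def test_reference_row_has_no_beta(self):
        frame = self.frame_with_effect(10.0)
        res = component_regression(frame, parameters=["ratio_score"])["ratio_score"]
        ref = res.component_betas.loc[res.component_betas["reference"]]
        assert len(ref) == 1 and ref.iloc[0]["score"] == 4
        assert math.isnan(ref.iloc[0]["beta"])

    def test_effect_recovered_on_proportion_scale(self):
        # a +15 point dMSS effect is a +0.15 beta on the 0-1 outcome scale
        frame = self.frame_with_effect(15.0, seed=2)
        res = component_regression(frame, parameters=["ratio_score"])["ratio_score"]
        top = res.component_betas.set_index("score").loc[12]
        assert top["ci_low"] <= 0.15 <= top["ci_high"]
        assert res.p_value < 0.001

    def test_single_category_parameter_skipped(self):
        frame = pd.DataFrame(
            {"crd_score": [6] * 10, "delta24_pct": np.linspace(0, 90, 10)}
        )
        assert component_regression(frame, parameters=["crd_score"]) == {}


class TestRmAnova:
    def test_identical_columns_give_zero_f(self):
        mat = np.tile(np.array([[3.0], [7.0], [5.0]]), (1, 3))
        res = rm_anova(mat)
        assert res.f_stat == 0.0

    def test_toy_matrix_matches_hand_partition(self):
        mat = [[80.0, 30.0, 25.0], [75.0, 40.0, 30.0], [90.0, 35.0, 20.0]]
        res = rm_anova(np.array(mat))
        assert res.f_stat == pytest.approx(rm_anova_f_by_hand(mat), rel=1e-10)
        assert res.df == (2.0, 4.0)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        mat = rng.normal(50, 10, size=(20, 3))
        res = rm_anova(mat)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 3),
                "time": np.tile(["T0", "T12", "T24"], 20),
                "value": mat.ravel(),
            }
        )
        ref = pg.rm_anova(
            data=long, dv="value", within="time", subject="subject"
        ).iloc[0]
        assert res.f_stat == pytest.approx(float(ref["F"]), rel=1e-6)
        assert res.p_value == pytest.approx(float(ref["p_unc"]), rel=1e-6)

    def test_missing_cell_rejected(self):
        mat = np.array([[1.0, 2.0, 3.0], [4.0, np.nan, 6.0]])
        with pytest.raises(DegenerateDesignError, match="completer"):
            rm_anova(mat)

    def test_pairwise_bonferroni_inflates_p(self):
        rng = np.random.default_rng(6)
        mat = rng.normal(size=(15, 3))
        plain = dict(rm_anova(mat, posthoc="uncorrected").pairwise)
        bonf = dict(rm_anova(mat, posthoc="bonferroni").pairwise)
        for pair in plain:
            assert bonf[pair] == pytest.approx(min(1.0, 3 * plain[pair]))

    def test_gg_correction_shrinks_df(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(size=(12, 3))
        plain = rm_anova(mat)
        gg = rm_anova(mat, correction="gg")
        assert gg.df[0] <= plain.df[0] and gg.df[1] <= plain.df[1]
        assert gg.f_stat == pytest.approx(plain.f_stat)


class TestOnewayAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        values = np.concatenate([a, b])
        groups = ["a"] * 30 + ["b"] * 25
        res = oneway_anova_posthoc(values, groups)
        from scipy.stats import ttest_ind

        t = ttest_ind(a, b).statistic
        assert res.f_stat == pytest.approx(t**2, rel=1e-10)
        assert res.pairwise == ()  # post hoc only for >= 3 groups

    def test_toy_three_groups_match_hand_partition(self):
        samples = [[1.0, 2.0, 3.0], [4.0, 6.0], [8.0, 9.0, 10.0, 11.0]]
        values = [x for g in samples for x in g]
        groups = ["g1"] * 3 + ["g2"] * 2 + ["g3"] * 4
        res = oneway_anova_posthoc(values, groups)
        assert res.f_stat == pytest.approx(oneway_f_by_hand(samples), rel=1e-10)
        assert res.df == (2, 6)
        assert len(res.pairwise) == 3

    def test_separated_groups_all_pairwise_significant(self):
        rng = np.random.default_rng(9)
        values = np.concatenate(
            [rng.normal(0, 1, 30), rng.normal(5, 1, 30), rng.normal(10, 1, 30)]
        )
        groups = ["lo"] * 30 + ["mid"] * 30 + ["hi"] * 30
        res = oneway_anova_posthoc(values, groups, posthoc="tukey")
        assert all(p < 0.001 for _, p in res.pairwise)

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateDesignError):
            oneway_anova_posthoc([1.0, 2.0], ["a", "a"])
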