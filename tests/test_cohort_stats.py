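import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from pedinirs.cohort_stats import (
    AGE_CLUSTERS,
    SCHOLKMANN_WOLF_PARAMS,
    DPFModelParams,
    assign_age_cluster,
    classify_correlation,
    cluster_summary,
    dpf_general_equation,
    pearson_with_p,
    pooled_total,
    refit_alpha,
    repositioning_cv,
)
from pedinirs.core_io import CohortRangeWarning


class TestAgeClusters:
    def test_clusters_partition_two_to_eighteen(self):
        assert [c.lower for c in AGE_CLUSTERS] == [2, 4, 6, 8, 10, 12, 14, 16]
        assert all(c.upper - c.lower == 2 for c in AGE_CLUSTERS)

    @pytest.mark.parametrize(
        "age,label",
        [(3.0, "2 to 4"), (4.0, "4 to 6"), (15.99, "14 to 16"), (16.0, "16 to 18"),
         (18.0, "16 to 18"), (2.0, "2 to 4")],
    )
    def test_half_open_assignment_with_closed_top(self, age, label):
        assert assign_age_cluster(age).label == label

    def test_out_of_range_age_warns(self):
        with pytest.warns(CohortRangeWarning):
            cluster = assign_age_cluster(25.0)
        assert cluster.label == "16 to 18"


class TestClusterSummary:
    def test_hand_computed_mean_and_sd(self):
        df = pd.DataFrame(
            {"age_years": [3, 3, 3], "gender": ["F"] * 3, "x": [10.0, 12.0, 14.0]}
        )
        s = cluster_summary(df, "x", gender="F")
        row = s[s["cluster"] == "2 to 4"].iloc[0]
        assert row["mean"] == pytest.approx(12.0)
        assert row["sd"] == pytest.approx(2.0)

    def test_single_record_has_undefined_sd(self):
        df = pd.DataFrame({"age_years": [3], "gender": ["F"], "x": [10.0]})
        row = cluster_summary(df, "x").iloc[0]
        assert row["mean"] == 10.0 and np.isnan(row["sd"])

    def test_pooled_total_of_summaries_is_the_grand_mean(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"age_years": rng.uniform(2, 18, 200), "x": rng.normal(50, 5, 200)}
        )
        s = cluster_summary(df, "x")
        assert pooled_total(s["mean"], s["n"]) == pytest.approx(df["x"].mean())


class TestPooledTotal:
    def test_single_cluster_is_identity(self):
        assert pooled_total([12.5], [7]) == 12.5

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            pooled_total([1.0, 2.0], [3])
        with pytest.raises(ValueError):
            pooled_total([1.0], [0])


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_with_p(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-10
        assert res.class_label == "high"

    def test_hand_computed_product_moment(self):
        res = pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_null_p_values_are_uniform(self):
        """Under independence the t-transform p-value is U(0,1)."""
        rng = np.random.default_rng(99)
        pvals = [
            pearson_with_p(rng.normal(size=8), rng.normal(size=8)).p_value
            for _ in range(3000)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3


class TestClassification:
    @pytest.mark.parametrize(
        "r,label",
        [(0.0, "none"), (0.29, "none"), (0.3, "low"), (-0.4, "low"), (-0.5, "moderate"),
         (0.69, "moderate"), (0.7, "high"), (-1.0, "high")],
    )
    def test_threshold_mapping(self, r, label):
        assert classify_correlation(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_correlation(1.0001)

    def test_monotone_and_exhaustive_on_unit_interval(self):
        order = {"none": 0, "low": 1, "moderate": 2, "high": 3}
        grid = np.linspace(0, 1, 101)
        labels = [order[classify_correlation(r)] for r in grid]
        assert labels == sorted(labels)
        assert set(labels) == {0, 1, 2, 3}


class TestRepositioningCV:
    def test_identical_values_have_zero_cv(self):
        assert repositioning_cv([3.3] * 5) == 0.0

    def test_hand_computed_example(self):
        assert repositioning_cv([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    @given(
        values=st.lists(st.floats(1.0, 100.0), min_size=2, max_size=8),
        k=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, values, k):
        try:
            base = repositioning_cv(values)
        except ValueError:
            return  # degenerate zero-mean draw
        assert repositioning_cv([k * v for v in values]) == pytest.approx(base, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            repositioning_cv([1.0])
        with pytest.raises(ValueError):
            repositioning_cv([-1.0, 1.0])


class TestDPFGeneralEquation:
    def test_degenerate_coefficients_reduce_to_offset(self):
        params = DPFModelParams(alpha=5.0, beta=0, gamma=1, delta=0, epsilon=0, zeta=0)
        for age in (2.0, 10.0, 18.0):
            assert dpf_general_equation(params, age, 830.0) == 5.0

    def test_matches_direct_polynomial_evaluation(self):
        p = SCHOLKMANN_WOLF_PARAMS
        age, lam = 7.5, 686.0
        direct = (
            p.alpha + p.beta * age**p.gamma
            + p.delta * lam**3 + p.epsilon * lam**2 + p.zeta * lam
        )
        assert dpf_general_equation(p, age, lam) == pytest.approx(direct, rel=1e-12)

    def test_positive_and_plausible_over_validity_range(self):
        for age in np.linspace(2, 18, 9):
            for lam in (686.0, 830.0):
                dpf = dpf_general_equation(SCHOLKMANN_WOLF_PARAMS, age, lam)
                assert 3.0 < dpf < 8.0

    def test_nondecreasing_in_age(self):
        values = [
            dpf_general_equation(SCHOLKMANN_WOLF_PARAMS, age, 830.0)
            for age in np.linspace(2, 18, 17)
        ]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestAlphaRefit:
    def _observations(self, shift=0.0):
        return [
            (age, lam, dpf_general_equation(SCHOLKMANN_WOLF_PARAMS, age, lam) + shift)
            for age in np.linspace(2, 18, 17)
            for lam in (686.0, 830.0)
        ]

    def test_noiseless_recovery_is_exact(self):
        assert refit_alpha(self._observations()) == pytest.approx(223.3, abs=1e-9)

    def test_shifted_observations_shift_alpha(self):
        alpha_hat = refit_alpha(self._observations(shift=-1.1))
        assert alpha_hat == pytest.approx(222.2, abs=1e-9)
        rel_change = 100.0 * (223.3 - alpha_hat) / 223.3
        assert rel_change < 0.5

    def test_refit_never_increases_mean_squared_error(self):
        rng = np.random.default_rng(1)
        obs = [
            (age, lam, dpf + rng.normal(0, 0.3))
            for age, lam, dpf in self._observations(shift=-0.7)
        ]
        p = SCHOLKMANN_WOLF_PARAMS
        alpha_hat = refit_alpha(obs, p)

        def mse(alpha):
            return np.mean(
                [
                    (dpf - (dpf_general_equation(p, a, l) - p.alpha + alpha)) ** 2
                    for a, l, dpf in obs
                ]
            )

        assert mse(alpha_hat) <= mse(p.alpha)

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            refit_alpha([])
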