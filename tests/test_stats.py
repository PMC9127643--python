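"""Effect sizes, correlations, regression, norms, and paired comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from speedcog.records import IntegrityError
from speedcog.stats import (
    CollinearityError,
    DegenerateInputError,
    cohen_d,
    cohen_d_from_samples,
    cohen_q,
    ols_regression,
    partial_correlation,
    pearson_r,
    weighted_group_norms,
    within_person_device_comparison,
)

finite = st.floats(-50, 50, allow_nan=False)
sds = st.floats(0.1, 20)
ns = st.integers(5, 5000)


class TestCohenD:
    def test_published_baseline_row(self):
        d, lo, hi = cohen_d(1.04, 0.56, 2820, 1.09, 0.80, 3309)
        assert d == pytest.approx(0.07, abs=0.005)
        assert lo == pytest.approx(0.02, abs=0.005)
        assert hi == pytest.approx(0.12, abs=0.005)

    def test_equal_means_give_zero_symmetric_ci(self):
        d, lo, hi = cohen_d(3.0, 1.0, 50, 3.0, 1.5, 60)
        assert d == 0.0
        assert lo == pytest.approx(-hi)

    def test_hand_computed_pooled_sd(self):
        # groups {1,2,3} and {3,4,5}: pooled SD 1, mean difference 2
        d, _, _ = cohen_d_from_samples([1, 2, 3], [3, 4, 5])
        assert d == pytest.approx(2.0)

    @settings(max_examples=50, deadline=None)
    @given(m1=finite, m2=finite, s1=sds, s2=sds, n1=ns, n2=ns)
    def test_antisymmetry_and_scale_invariance(self, m1, m2, s1, s2, n1, n2):
        d, _, _ = cohen_d(m1, s1, n1, m2, s2, n2)
        d_swapped, _, _ = cohen_d(m2, s2, n2, m1, s1, n1)
        assert d == pytest.approx(-d_swapped, abs=1e-12)
        d_scaled, _, _ = cohen_d(3 * m1, 3 * s1, n1, 3 * m2, 3 * s2, n2)
        assert d_scaled == pytest.approx(d, rel=1e-9, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            cohen_d(1, 0.0, 10, 2, 1.0, 10)
        with pytest.raises(DegenerateInputError):
            cohen_d(1, 1.0, 1, 2, 1.0, 10)


class TestPearsonR:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])


class TestCohenQ:
    @pytest.mark.parametrize(
        "r1,r2,expected",
        [
            (0.38, 0.32, 0.07),
            (0.35, 0.43, -0.09),
            (0.48, 0.50, -0.03),
            (-0.61, -0.49, -0.17),
            (0.56, 0.45, 0.15),
        ],
    )
    def test_published_correlation_contrasts(self, r1, r2, expected):
        assert round(cohen_q(r1, r2), 2) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(r1=st.floats(-0.99, 0.99), r2=st.floats(-0.99, 0.99))
    def test_antisymmetry_and_zero_diagonal(self, r1, r2):
        assert cohen_q(r1, r2) == pytest.approx(-cohen_q(r2, r1), abs=1e-12)
        assert cohen_q(r1, r1) == 0.0

    def test_domain_error(self):
        with pytest.raises(DegenerateInputError):
            cohen_q(1.0, 0.5)


class TestOLS:
    def test_intercept_only_recovers_mean(self):
        y = pd.Series([1.0, 2.0, 3.0, 7.0, 9.0])
        fit = ols_regression(y, pd.DataFrame(index=y.index))
        assert fit.loc["const", "b"] == pytest.approx(y.mean())

    def test_noiseless_outcome_recovered_exactly(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"x1": rng.normal(size=30)})
        y = 2 * x["x1"] - 1
        fit = ols_regression(y, x)
        assert fit.loc["x1", "b"] == pytest.approx(2.0)
        assert fit.loc["const", "b"] == pytest.approx(-1.0)

    def test_matches_normal_equations_oracle(self):
        """Coefficients equal (X'X)^-1 X'y computed by hand to 1e-10."""
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        y = pd.Series(rng.normal(size=50))
        fit = ols_regression(y, X)
        Xc = np.column_stack([np.ones(50), X.to_numpy()])
        beta = np.linalg.inv(Xc.T @ Xc) @ Xc.T @ y.to_numpy()
        np.testing.assert_allclose(fit["b"].to_numpy(), beta, atol=1e-10)
        # SEs from the classical covariance matrix
        resid = y.to_numpy() - Xc @ beta
        s2 = resid @ resid / (50 - 4)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(Xc.T @ Xc)))
        np.testing.assert_allclose(fit["se"].to_numpy(), se, atol=1e-10)

    def test_collinearity_names_offending_column(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=40)})
        X["twice_a"] = 2 * X["a"]
        with pytest.raises(CollinearityError, match="twice_a"):
            ols_regression(pd.Series(rng.normal(size=40)), X)


class TestPartialCorrelation:
    def test_empty_controls_reduce_to_pearson(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 100))
        assert partial_correlation(x, y, None) == pytest.approx(pearson_r(x, y))

    def test_independent_controls_leave_r_nearly_unchanged(self):
        rng = np.random.default_rng(4)
        n = 10_000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        controls = pd.DataFrame({"c": rng.normal(size=n)})
        r0 = pearson_r(x, y)
        rp = partial_correlation(x, y, controls)
        assert abs(rp - r0) < 3 / np.sqrt(n)

    def test_outcome_determined_by_control_gives_zero(self):
        rng = np.random.default_rng(5)
        c = rng.normal(size=200)
        x = rng.normal(size=200)
        y = 3 * c + 1
        with pytest.raises(DegenerateInputError):
            partial_correlation(x, y, pd.DataFrame({"c": c}))

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        n = 500
        c = rng.normal(size=n)
        x = 0.4 * c + rng.normal(size=n)
        y = 0.3 * c + 0.2 * x + rng.normal(size=n)
        data = pd.DataFrame({"x": x, "y": y, "c": c})
        expected = float(
            pingouin.partial_corr(data, x="x", y="y", covar="c")["r"].iloc[0]
        )
        got = partial_correlation(x, y, data[["c"]])
        assert got == pytest.approx(expected, abs=1e-10)


class TestWeightedNorms:
    def test_equal_weights_equal_unweighted_mean_and_ci(self):
        rng = np.random.default_rng(7)
        x = rng.normal(50, 10, 400)
        ages = rng.integers(18, 102, 400)
        norms = weighted_group_norms(x, np.ones(400), ages)
        frame = pd.DataFrame({"x": x, "age": ages})
        from speedcog.records import age_group_label

        frame["g"] = [age_group_label(a) for a in frame["age"]]
        for row in norms.itertuples():
            grp = frame.loc[frame["g"] == row.age_group, "x"].to_numpy()
            assert row.weighted_mean == pytest.approx(grp.mean(), abs=1e-12)
            se = grp.std(ddof=0) / np.sqrt(len(grp))
            assert row.ci_low == pytest.approx(grp.mean() - 1.959963984540054 * se,
                                               abs=1e-12)

    def test_hand_computed_weighted_mean(self):
        norms = weighted_group_norms([40.0, 44.0], [1.0, 3.0], [20, 25])
        row = norms.loc[norms["age_group"] == "18-34"].iloc[0]
        assert row["weighted_mean"] == pytest.approx(43.0)

    def test_singleton_group_has_mean_but_no_ci(self):
        norms = weighted_group_norms([40.0], [2.0], [80])
        row = norms.loc[norms["age_group"] == ">=75"].iloc[0]
        assert row["weighted_mean"] == pytest.approx(40.0)
        assert np.isnan(row["ci_low"]) and np.isnan(row["ci_high"])

    def test_groups_partition_all_ages(self):
        rng = np.random.default_rng(8)
        ages = rng.integers(18, 102, 500)
        norms = weighted_group_norms(np.ones(500), np.ones(500), ages)
        assert norms["n_unweighted"].sum() == 500


class TestWithinPerson:
    @staticmethod
    def _paired(values_kb, values_tc):
        n = len(values_kb)
        return pd.DataFrame(
            {
                "respondent_id": [f"R{i}" for i in range(n)] * 2,
                "device_type": ["keyboard"] * n + ["touchscreen"] * n,
                "score": list(values_kb) + list(values_tc),
            }
        )

    def test_identical_scores_flag_undefined_paired_d(self):
        scores = self._paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        cmp = within_person_device_comparison(scores)
        assert cmp.mean_diff == 0.0 and cmp.paired_d is None

    def test_constant_offset(self):
        kb = [1.0, 1.5, 2.0, 2.5]
        scores = self._paired(kb, [v + 0.1 for v in kb])
        cmp = within_person_device_comparison(scores)
        assert cmp.mean_diff == pytest.approx(0.1)
        assert cmp.cross_device_r == pytest.approx(1.0)

    def test_duplicate_device_entries_rejected(self):
        scores = self._paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        dup = pd.concat([scores, scores.iloc[[0]]])
        with pytest.raises(IntegrityError):
            within_person_device_comparison(dup)

    def test_cross_device_r_matches_variance_ratio_oracle(self):
        """Paired medians correlate at sigma_person^2/(sigma_person^2+var(median)).

        The oracle simulates the generative law directly at large n.
        """
        rng = np.random.default_rng(9)
        sigma_p, sigma_t, n_trials = 0.25, 0.20, 23
        n_oracle = 120_000

        def paired_medians(n):
            u = rng.normal(0, sigma_p, n)
            m1 = np.median(rng.normal(0, sigma_t, (n, n_trials)), axis=1) + u
            m2 = np.median(rng.normal(0, sigma_t, (n, n_trials)), axis=1) + u
            return m1, m2

        m1, m2 = paired_medians(n_oracle)
        r_oracle = np.corrcoef(m1, m2)[0, 1]

        n = 3000
        s1, s2 = paired_medians(n)
        scores = self._paired(s1, s2)
        cmp = within_person_device_comparison(scores)
        se = (1 - r_oracle**2) / np.sqrt(n - 3)
        assert abs(cmp.cross_device_r - r_oracle) <= 3 * se
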