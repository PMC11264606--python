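import numpy as np
import pandas as pd
import pytest

from prefscore.agreement import (
    PairedSample,
    agreement_report,
    anova_decompose,
    cohen_d_to_r,
    concordance_from_moments,
    correlation_matrix,
    icc_two_way_mixed,
    icc_two_way_random,
    nmae,
)
from prefscore.exceptions import (
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)
from prefscore.synthetic import bivariate_moment_sample


def brute_force_anova(data):
    """Independent oracle: explicit loops over the two-way layout."""
    n, k = data.shape
    grand = data.mean()
    ss_between = ss_time = ss_within = 0.0
    row_means = [data[i].mean() for i in range(n)]
    col_means = [data[:, j].mean() for j in range(k)]
    for i in range(n):
        ss_between += k * (row_means[i] - grand) ** 2
    for j in range(k):
        ss_time += n * (col_means[j] - grand) ** 2
    for i in range(n):
        for j in range(k):
            ss_within += (data[i, j] - row_means[i] - col_means[j] + grand) ** 2
    return ss_between / (n - 1), ss_within / ((n - 1) * (k - 1)), ss_time / (k - 1)


class TestAnovaDecomposition:
    def test_identical_columns_have_no_interaction_or_time_effect(self, rng):
        x = rng.normal(size=20)
        d = anova_decompose(PairedSample(x, x.copy()))
        assert d.ms_within == pytest.approx(0, abs=1e-14)
        assert d.ms_time == pytest.approx(0, abs=1e-14)

    def test_four_row_worked_example_matches_hand_sums(self):
        data = np.array([[0.9, 0.5], [0.7, 0.6], [1.0, 0.8], [0.4, 0.1]])
        d = anova_decompose(PairedSample(data[:, 0], data[:, 1]))
        msb, msw, mst = brute_force_anova(data)
        assert d.ms_between == pytest.approx(msb, abs=1e-12)
        assert d.ms_within == pytest.approx(msw, abs=1e-12)
        assert d.ms_time == pytest.approx(mst, abs=1e-12)

    def test_constant_columns_offset_by_c(self):
        n, c = 8, 0.3
        d = anova_decompose(PairedSample(np.full(n, 1.0), np.full(n, 1.0 - c)))
        # column means differ by c around the grand mean: SS_time = n c^2 / 2, df = 1
        assert d.ms_time == pytest.approx(n * c**2 / 2, abs=1e-12)
        assert d.ms_between == pytest.approx(0, abs=1e-14)

    def test_sums_of_squares_conserved(self, rng):
        x, y = rng.normal(size=(2, 500))
        d = anova_decompose(PairedSample(x, y))
        data = np.column_stack([x, y])
        ss_total = np.sum((data - data.mean()) ** 2)
        recon = (d.n - 1) * d.ms_between + d.ms_time + (d.n - 1) * d.ms_within
        assert recon == pytest.approx(ss_total, rel=1e-10)

    def test_single_row_raises(self):
        with pytest.raises(InsufficientDataError):
            PairedSample(np.array([1.0]), np.array([2.0]))


class TestICC:
    def test_identical_columns_give_one(self, rng):
        x = rng.normal(size=50)
        d = anova_decompose(PairedSample(x, x.copy()))
        assert icc_two_way_mixed(d) == pytest.approx(1.0)
        assert icc_two_way_random(d) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        x, y = bivariate_moment_sample(20_000, 0, 1, 0, 1, 1e-9, seed=5)
        d = anova_decompose(PairedSample(x, y))
        assert abs(icc_two_way_mixed(d)) < 0.01
        assert abs(icc_two_way_random(d)) < 0.01

    def test_absolute_agreement_matches_moment_closed_form(self):
        """ICC(A,1) converges to the concordance correlation from sample moments."""
        x, y = bivariate_moment_sample(10_000, 0.855, 0.195, 0.539, 0.249, 0.69, seed=2)
        icc = icc_two_way_random(anova_decompose(PairedSample(x, y)))
        ccc = concordance_from_moments(0.855, 0.195, 0.539, 0.249, 0.69)
        assert icc == pytest.approx(ccc, abs=0.005)

    def test_matches_pingouin_on_small_sample(self, rng):
        pg = pytest.importorskip("pingouin")
        x, y = rng.normal(size=(2, 30))
        y = y + 0.4
        d = anova_decompose(PairedSample(x, y))
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(30), 2),
                "raters": np.tile(["a", "b"], 30),
                "scores": np.column_stack([x, y]).ravel(),
            }
        )
        icc_table = pg.intraclass_corr(long, targets="targets", raters="raters", ratings="scores")
        icc_table = icc_table.set_index("Type")["ICC"]
        absolute = icc_table.get("ICC2", icc_table.get("ICC(A,1)"))
        consistency = icc_table.get("ICC3", icc_table.get("ICC(C,1)"))
        assert icc_two_way_random(d) == pytest.approx(absolute, abs=1e-9)
        assert icc_two_way_mixed(d) == pytest.approx(consistency, abs=1e-9)

    def test_mixed_at_least_random_when_means_differ(self, rng):
        for _ in range(5):
            x = rng.normal(size=200)
            y = 0.7 * x + rng.normal(scale=0.5, size=200) + 0.3
            d = anova_decompose(PairedSample(x, y))
            assert icc_two_way_mixed(d) >= icc_two_way_random(d) - 1e-12

    def test_degenerate_between_variance_raises(self):
        d = anova_decompose(PairedSample(np.full(5, 1.0), np.full(5, 1.0)))
        with pytest.raises(UndefinedStatisticError):
            icc_two_way_mixed(d)


class TestNMAE:
    def test_perfect_prediction_is_zero(self, rng):
        x = rng.normal(size=40)
        assert nmae(x, x) == 0.0

    def test_hand_computed_example(self):
        # mean |obs - pred| = 1, SD(obs) = sqrt(2) with the n-1 denominator
        assert nmae([0.0, 2.0], [1.0, 1.0]) == pytest.approx(1 / np.sqrt(2))

    def test_scale_invariance(self, rng):
        x, y = rng.normal(size=(2, 50))
        assert nmae(3.7 * x, 3.7 * y) == pytest.approx(nmae(x, y), rel=1e-12)

    def test_constant_observed_raises(self):
        with pytest.raises(UndefinedStatisticError):
            nmae([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCohenConversion:
    @pytest.mark.parametrize("d,expected", [(0.2, 0.100), (0.5, 0.243), (0.8, 0.371)])
    def test_rule_of_thumb_values(self, d, expected):
        assert cohen_d_to_r(d) == pytest.approx(expected, abs=5e-4)

    def test_odd_and_bounded(self, rng):
        d = rng.normal(scale=3, size=100)
        r = cohen_d_to_r(d)
        assert np.allclose(r, -cohen_d_to_r(-d))
        assert np.all(np.abs(r) < 1)


class TestCorrelationMatrix:
    def test_self_and_antimonotone(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [5.0, 4, 3, 2, 1]})
        r, p, n = correlation_matrix(df)
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(-1.0)

    def test_five_row_worked_table(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [2.0, 4, 5, 4, 5]})
        r, p, n = correlation_matrix(df)
        # hand computation: cov = 1.5, var_x = 2.5, var_y = 1.5
        assert r.loc["x", "y"] == pytest.approx(1.5 / np.sqrt(2.5 * 1.5), abs=1e-12)
        assert n.loc["x", "y"] == 5

    def test_constant_column_flagged_undefined(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "c": [2.0, 2, 2]})
        r, p, _ = correlation_matrix(df)
        assert np.isnan(r.loc["a", "c"]) and np.isnan(p.loc["a", "c"])

    def test_pairwise_complete_case(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, np.nan, 5], "b": [2.0, 1, 4, 8, np.nan]})
        _, _, n = correlation_matrix(df)
        assert n.loc["a", "b"] == 3

    def test_unknown_variable_raises(self):
        with pytest.raises(ValidationError):
            correlation_matrix(pd.DataFrame({"a": [1.0, 2]}), ["a", "zz"])


class TestAgreementReport:
    def test_moment_matched_study_sample(self):
        x, y = bivariate_moment_sample(20_000, 0.855, 0.195, 0.539, 0.249, 0.69, seed=3)
        rep = agreement_report(x, y)
        assert rep.pearson_r == pytest.approx(0.69, abs=1e-9)
        assert rep.mean_difference == pytest.approx(0.316, abs=1e-9)
        assert rep.n == 20_000

    def test_complete_case_filtering(self):
        rep = agreement_report([1.0, 2, np.nan, 4], [1.1, np.nan, 3, 4.2])
        assert rep.n == 2
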