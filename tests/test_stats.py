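import numpy as np
import pandas as pd
import pytest

from mumri import (
    ConsistencyError,
    DegenerateInputError,
    agreement,
    compare_groups,
    correlate,
    icc_absolute_agreement,
    normality_test,
    validate_metric_table,
)

from _references import (
    A10,
    B10,
    PEARSON_P_X8Y8,
    PEARSON_R_X8Y8,
    SHAPIRO_P_X10,
    SHAPIRO_W_X10,
    X8,
    X10,
    Y8,
)


class TestNormality:
    def test_matches_reference_implementation(self):
        w, p = normality_test(X10)
        assert w == pytest.approx(SHAPIRO_W_X10, abs=1e-6)
        assert p == pytest.approx(SHAPIRO_P_X10, abs=1e-6)

    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        over = sum(normality_test(rng.normal(0, 1, 31)).p_value > 0.05 for _ in range(100))
        assert over >= 90

    def test_constant_input_is_undefined(self):
        with pytest.raises(DegenerateInputError):
            normality_test([3.0, 3.0, 3.0, 3.0])


class TestCompareGroups:
    def _table(self, groups, key="muscle"):
        rows = []
        for name, values in groups.items():
            rows += [{key: name, "value": v} for v in values]
        return pd.DataFrame(rows)

    def test_identical_groups_give_zero_t(self):
        vals = [20.0, 25.0, 30.0, 35.0]
        table = pd.DataFrame(
            {"age": [30] * 4 + [50] * 4, "value": vals + vals}
        )
        res = compare_groups(table, "value", "age")
        assert res.statistic == pytest.approx(0.0)
        assert res.df == (6,)

    def test_anova_degrees_of_freedom(self):
        rng = np.random.default_rng(1)
        table = self._table({m: rng.normal(25, 5, 10) for m in ("EDL", "PL", "TA")})
        res = compare_groups(table, "value", "muscle")
        assert res.test == "anova"
        assert res.df == (2, 27)
        assert 0.0 <= res.p_value <= 1.0

    def test_type_one_error_calibrated(self):
        # equal-mean groups at the in-vivo band sizes (13 vs 18): p ~ U(0,1)
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(1000):
            table = pd.DataFrame(
                {
                    "age": [30] * 18 + [50] * 13,
                    "value": rng.normal(10.0, 3.0, 31),
                }
            )
            pvals.append(compare_groups(table, "value", "age").p_value)
        grid = np.linspace(0, 1, 101)
        ks = np.max(np.abs(np.mean(np.asarray(pvals)[:, None] <= grid, axis=0) - grid))
        assert ks < 0.1

    def test_undersized_group_rejected(self):
        table = pd.DataFrame({"muscle": ["TA", "TA", "PL"], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            compare_groups(table, "value", "muscle")


class TestAgreement:
    def test_identical_observers_are_perfect(self):
        res = agreement(A10, A10)
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.bias == 0.0
        assert res.coefficient_of_repeatability == 0.0

    def test_constant_offset_shows_as_bias_only(self):
        res = agreement(A10, np.asarray(A10) + 2.5)
        assert res.bias == pytest.approx(2.5)
        assert res.coefficient_of_repeatability == pytest.approx(0.0, abs=1e-9)
        assert res.icc < 1.0

    def test_matches_mean_squares_closed_form(self):
        # independent route: explicit two-way ANOVA mean squares
        y = np.column_stack([A10, B10])
        n, k = y.shape
        grand = y.mean()
        msr = k * ((y.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((y.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((y - y.mean(1)[:, None] - y.mean(0)[None, :] + grand) ** 2).sum() / (
            (n - 1) * (k - 1)
        )
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        got = agreement(A10, B10)
        assert got.icc == pytest.approx(expected, abs=1e-8)
        from _references import ICC_A1_AB
        assert got.icc == pytest.approx(ICC_A1_AB, abs=1e-6)

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(10), 2),
                "raters": np.tile(["A", "B"], 10),
                "ratings": np.column_stack([A10, B10]).ravel(),
            }
        )
        table = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
        types = table["Type"].astype(str)
        ref_single = float(table.loc[types.isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0])
        ref_average = float(table.loc[types.isin(["ICC2k", "ICC(A,k)"]), "ICC"].iloc[0])
        y = np.column_stack([A10, B10])
        assert icc_absolute_agreement(y, "single") == pytest.approx(ref_single, abs=1e-8)
        assert icc_absolute_agreement(y, "average") == pytest.approx(ref_average, abs=1e-8)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            agreement([1.0, 2.0], [1.0, 2.0])


class TestCorrelate:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_reference_implementation(self):
        res = correlate(X8, Y8)
        assert res.r == pytest.approx(PEARSON_R_X8Y8, abs=1e-10)
        assert res.p_value == pytest.approx(PEARSON_P_X8Y8, abs=1e-10)

    def test_null_rejection_rate_is_nominal(self):
        rng = np.random.default_rng(3)
        hits = sum(
            correlate(rng.normal(0, 1, 31), rng.normal(0, 1, 31)).p_value < 0.05
            for _ in range(1000)
        )
        assert 25 <= hits <= 80  # ~5% +- binomial noise

    def test_zero_variance_is_undefined(self):
        with pytest.raises(DegenerateInputError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMetricTable:
    def test_duplicate_keys_rejected(self):
        table = pd.DataFrame(
            {
                "subject": [1, 1],
                "unit": [0, 0],
                "observer": ["A", "A"],
                "scan": [0, 0],
                "csa_mm2": [20.0, 21.0],
            }
        )
        with pytest.raises(ConsistencyError):
            validate_metric_table(table)

    def test_affine_invariance_of_t_and_icc_behaviour(self):
        rng = np.random.default_rng(4)
        a = rng.normal(25, 8, 12)
        b = a + rng.normal(0, 1.5, 12)
        base = agreement(a, b)
        scaled = agreement(3.0 * a + 7.0, 3.0 * b + 7.0)
        assert scaled.icc == pytest.approx(base.icc, abs=1e-10)
        assert scaled.bias == pytest.approx(3.0 * base.bias, abs=1e-9)
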