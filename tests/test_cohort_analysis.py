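import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bivakit.cohort_analysis import (
    FFM_SDS_SCHEME,
    HFFM_SDS_SCHEME,
    CategoryScheme,
    categorize,
    correlation_matrix,
    group_contrasts,
    slope_heterogeneity,
    standardized_regression,
)
from bivakit.errors import CollinearityError, DomainError


class TestCategorize:
    def test_published_band_examples(self):
        table = pd.DataFrame({"ffm_sds": [-1.2], "hffm_sds": [-0.5]})
        labels, _ = categorize(table, FFM_SDS_SCHEME)
        assert labels.iloc[0] == "FFM1"  # below -1.0
        labels, _ = categorize(table, HFFM_SDS_SCHEME)
        assert labels.iloc[0] == "H2"  # right-closed: -0.5 belongs to (-1, -0.5]

    def test_all_values_below_first_break(self):
        table = pd.DataFrame({"ffm_sds": [-2.0, -3.0, -1.5]})
        labels, counts = categorize(table, FFM_SDS_SCHEME)
        assert (labels == "FFM1").all()
        assert counts.sum() == 3
        assert set(counts.index) == set(FFM_SDS_SCHEME.labels)

    def test_left_closed_boundary_rule(self):
        scheme = CategoryScheme("x", (0.0,), ("lo", "hi"), boundary_rule="left_closed")
        labels, _ = categorize(pd.DataFrame({"x": [0.0]}), scheme)
        assert labels.iloc[0] == "hi"  # [0, inf) owns the boundary

    @given(st.lists(st.floats(min_value=-4, max_value=4), min_size=1, max_size=60))
    def test_partition_property(self, values):
        table = pd.DataFrame({"ffm_sds": values})
        labels, counts = categorize(table, FFM_SDS_SCHEME)
        assert labels.notna().all()
        assert counts.sum() == len(values)

    def test_invalid_schemes_rejected(self):
        with pytest.raises(DomainError):
            CategoryScheme("x", (1.0, 0.0), ("a", "b", "c"))
        with pytest.raises(DomainError):
            CategoryScheme("x", (0.0,), ("a",))


class TestCorrelation:
    def test_diagonal_and_perfect_linearity(self):
        x = np.linspace(-2, 2, 30)
        table = pd.DataFrame({"a": x, "b": 2.0 * x, "c": np.sin(x)})
        r, p, flagged = correlation_matrix(table, ["a", "b", "c"])
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(r, r.T)
        assert flagged == []

    def test_specified_correlation_recovered_from_large_sample(self):
        rng = np.random.default_rng(303)
        z = rng.standard_normal((200_000, 2))
        rho = 0.73
        y = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
        r, _, _ = correlation_matrix(pd.DataFrame({"a": z[:, 0], "b": y}), ["a", "b"])
        assert r.loc["a", "b"] == pytest.approx(rho, abs=0.01)

    def test_zero_variance_column_flagged_not_silent(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0]})
        r, p, flagged = correlation_matrix(table, ["a", "b"])
        assert flagged == ["b"]
        assert np.isnan(r.loc["a", "b"])

    def test_subgroup_mask(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame({"a": rng.standard_normal(100), "b": rng.standard_normal(100)})
        mask = pd.Series(np.arange(100) < 50)
        r, _, _ = correlation_matrix(table, ["a", "b"], subgroup=mask)
        r_manual = np.corrcoef(table.a[:50], table.b[:50])[0, 1]
        assert r.loc["a", "b"] == pytest.approx(r_manual)

    def test_too_few_rows(self):
        with pytest.raises(DomainError):
            correlation_matrix(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}), ["a", "b"])


class TestRegression:
    def test_matches_explicit_normal_equations(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(
            {
                "y": rng.standard_normal(10),
                "x1": rng.standard_normal(10),
                "x2": rng.standard_normal(10),
            }
        )
        res = standardized_regression(table, "y", ["x1", "x2"])
        X = np.column_stack([np.ones(10), table.x1, table.x2])
        beta = np.linalg.solve(X.T @ X, X.T @ table.y.to_numpy())
        assert res.term("const").coefficient == pytest.approx(beta[0], abs=1e-10)
        assert res.term("x1").coefficient == pytest.approx(beta[1], abs=1e-10)
        assert res.term("x2").coefficient == pytest.approx(beta[2], abs=1e-10)
        # r2 equals 1 - SSE/SST computed independently
        resid = table.y.to_numpy() - X @ beta
        sst = np.sum((table.y - table.y.mean()) ** 2)
        assert res.r2 == pytest.approx(1 - resid @ resid / sst, abs=1e-10)

    def test_simple_regression_on_unit_sd_columns_equals_pearson_r(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(200)
        y = 0.6 * x + 0.8 * rng.standard_normal(200)
        x = x / x.std(ddof=1)
        y = y / y.std(ddof=1)
        table = pd.DataFrame({"y": y, "x": x})
        res = standardized_regression(table, "y", ["x"])
        r = np.corrcoef(x, y)[0, 1]
        assert res.term("x").coefficient == pytest.approx(r, abs=1e-12)

    def test_orthogonal_predictors_recover_marginal_correlations(self):
        n = 64
        t = np.arange(n)
        x1 = np.sqrt(2) * np.cos(2 * np.pi * t / n)
        x2 = np.sqrt(2) * np.sin(2 * np.pi * t / n)  # exactly orthogonal, mean 0
        y = 0.5 * x1 - 0.3 * x2
        table = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        res = standardized_regression(table, "y", ["x1", "x2"])
        assert res.term("x1").coefficient == pytest.approx(0.5, abs=1e-10)
        assert res.term("x2").coefficient == pytest.approx(-0.3, abs=1e-10)

    def test_collinearity_error_names_offending_column(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(30)
        table = pd.DataFrame({"y": rng.standard_normal(30), "x1": x, "x2": 2.0 * x})
        with pytest.raises(CollinearityError) as err:
            standardized_regression(table, "y", ["x1", "x2"])
        assert {"x1", "x2"} & set(err.value.columns)


class TestContrasts:
    @pytest.fixture
    def grouped_table(self):
        rng = np.random.default_rng(99)
        groups = np.repeat([f"g{i}" for i in range(5)], 40)
        y = rng.standard_normal(200)
        y[groups == "g4"] += 2.0  # one group shifted by 2 SD
        table = pd.DataFrame({"y": y})
        labels = pd.Series(pd.Categorical(groups))
        return table, labels

    def test_five_groups_give_ten_pairs(self, grouped_table):
        table, labels = grouped_table
        out = group_contrasts(table, "y", labels)
        assert len(out) == 10

    def test_shifted_group_flagged_others_mostly_not(self, grouped_table):
        table, labels = grouped_table
        out = group_contrasts(table, "y", labels)
        with_g4 = out[(out.group_a == "g4") | (out.group_b == "g4")]
        without_g4 = out[(out.group_a != "g4") & (out.group_b != "g4")]
        assert with_g4.significant.all()
        assert without_g4.significant.sum() <= 1

    def test_identical_groups_not_flagged(self):
        base = np.linspace(-1, 1, 20)
        table = pd.DataFrame({"y": np.concatenate([base, base])})
        labels = pd.Series(["a"] * 20 + ["b"] * 20)
        out = group_contrasts(table, "y", labels)
        assert out.p_bonferroni.iloc[0] == 1.0
        assert not out.significant.iloc[0]

    def test_bonferroni_never_below_raw_and_capped(self, grouped_table):
        table, labels = grouped_table
        out = group_contrasts(table, "y", labels)
        assert (out.p_bonferroni >= out.p_raw - 1e-15).all()
        assert (out.p_bonferroni <= 1.0).all()

    def test_singleton_group_flagged_with_undefined_p(self):
        table = pd.DataFrame({"y": [1.0, 2.0, 3.0, 9.0]})
        labels = pd.Series(["a", "a", "a", "b"])
        out = group_contrasts(table, "y", labels)
        assert np.isnan(out.p_raw.iloc[0])
        assert out.flag.iloc[0] == "singleton group"


class TestSlopeHeterogeneity:
    def _simulate(self, rng, slopes, n_per=60, noise=0.5):
        rows = []
        for g, slope in slopes.items():
            x = rng.standard_normal(n_per)
            y = slope * x + noise * rng.standard_normal(n_per)
            rows.append(pd.DataFrame({"x": x, "y": y, "g": g}))
        return pd.concat(rows, ignore_index=True)

    def test_null_model_rarely_flags_terms(self):
        rng = np.random.default_rng(31)
        hits = total = 0
        for _ in range(60):
            table = self._simulate(rng, {"a": 0.8, "b": 0.8, "c": 0.8}, n_per=40)
            res = slope_heterogeneity(table, "y", "x", table.g)
            inter = [t for t in res.terms if t.name.startswith("x:")]
            hits += sum(t.p_value < 0.05 for t in inter)
            total += len(inter)
        assert hits / total < 0.10  # per-term type-I near nominal

    def test_discordant_slope_detected(self):
        rng = np.random.default_rng(32)
        detected = 0
        for _ in range(20):
            table = self._simulate(rng, {"a": 0.3, "b": 0.3, "c": 0.8})
            res = slope_heterogeneity(table, "y", "x", table.g, reference="a")
            detected += res.term("x:group[c]").p_value < 0.05
        assert detected >= 18

    def test_reduces_to_simple_fit_without_group_structure(self):
        rng = np.random.default_rng(33)
        x = rng.standard_normal(300)
        y = 0.87 * x + 0.5 * rng.standard_normal(300)
        table = pd.DataFrame({"x": x, "y": y, "g": np.repeat(["a", "b", "c"], 100)})
        res = slope_heterogeneity(table, "y", "x", table.g)
        simple = standardized_regression(table, "y", ["x"])
        assert res.r2 == pytest.approx(simple.r2, abs=0.01)

    def test_tiny_groups_excluded_and_noted(self):
        rng = np.random.default_rng(34)
        table = self._simulate(rng, {"a": 0.5, "b": 0.5}, n_per=30)
        tiny = pd.DataFrame({"x": [0.1, 0.2], "y": [0.1, 0.2], "g": "tiny"})
        table = pd.concat([table, tiny], ignore_index=True)
        res = slope_heterogeneity(table, "y", "x", table.g)
        assert res.excluded_groups == ["tiny"]
        assert not any("tiny" in t.name for t in res.terms)
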