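"""Full-covariate model, sequential variance decomposition, rank-normal
adjustment and pairwise biomarker correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pqtlkit import covariates as cov


@pytest.fixture()
def simple_table(rng):
    n = 500
    df = pd.DataFrame(
        {
            "age": rng.uniform(15, 90, n),
            "sex": rng.integers(1, 3, n),
            "smoker": rng.integers(0, 2, n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    return cov.CovariateTable(df)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected",
        [(0.05, 158, 3.16e-4), (0.05, 4_840_842, 1.03e-8), (0.05, 1, 0.05)],
    )
    def test_thresholds(self, alpha, m, expected):
        got = cov.bonferroni_threshold(alpha, m)
        assert float(f"{got:.3g}") == pytest.approx(expected, rel=1e-6)

    def test_invalid(self):
        with pytest.raises(ValueError):
            cov.bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            cov.bonferroni_threshold(1.5, 10)


class TestFullModel:
    def test_recovers_planted_coefficient(self, simple_table, rng):
        age = simple_table.data["age"]
        y = pd.Series(2.0 * age + rng.normal(0, 0.1, len(age)), index=age.index, name="t")
        fit = cov.fit_full_model(y, simple_table)
        assert fit.params["age"] == pytest.approx(2.0, abs=0.01)
        dec = cov.variance_decomposition(fit)
        assert dec.fractions["age"] > 0.99

    def test_null_trait_no_term_significant(self, simple_table, rng):
        y = pd.Series(rng.normal(size=500), index=simple_table.data.index, name="t")
        fit = cov.fit_full_model(y, simple_table)
        assert (fit.pvalues > 0.05 / len(simple_table.names)).all()

    def test_constant_covariate_dropped(self, simple_table, rng):
        df = simple_table.data.copy()
        df["flat"] = 1.0
        table = cov.CovariateTable(df, kinds={"flat": "continuous"})
        y = pd.Series(rng.normal(size=len(df)), index=df.index, name="t")
        fit = cov.fit_full_model(y, table)
        assert "flat" in fit.dropped
        assert "flat" not in fit.terms

    def test_below_lod_cells_excluded(self, simple_table, rng):
        y = pd.Series(rng.normal(size=500), index=simple_table.data.index, name="t")
        y.iloc[:100] = np.nan
        fit = cov.fit_full_model(y, simple_table)
        assert fit.n == 400

    def test_too_few_cases_rejected(self, simple_table, rng):
        y = pd.Series(np.nan, index=simple_table.data.index, name="t")
        y.iloc[:3] = rng.normal(size=3)
        with pytest.raises(ValueError, match="complete cases"):
            cov.fit_full_model(y, simple_table)


class TestDecomposition:
    def test_orthogonal_design_matches_projection_oracle(self, rng):
        # orthogonalized covariates: sequential fractions equal the simple
        # per-covariate regression R^2 and are order-invariant
        n = 400
        raw = rng.normal(size=(n, 3))
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), raw]))
        X = q[:, 1:]  # mutually orthogonal, orthogonal to intercept
        y = X @ np.array([1.0, 2.0, 0.5]) + rng.normal(0, 1, n)
        idx = [f"s{i}" for i in range(n)]
        ys = pd.Series(y, index=idx, name="t")
        for order in ([0, 1, 2], [2, 0, 1]):
            cols = {f"c{j}": X[:, j] for j in order}
            table = cov.CovariateTable(pd.DataFrame(cols, index=idx))
            dec = cov.variance_decomposition(cov.fit_full_model(ys, table))
            total = np.sum((y - y.mean()) ** 2)
            for j in order:
                oracle = np.corrcoef(X[:, j], y)[0, 1] ** 2 * (
                    np.sum((y - y.mean()) ** 2) / total
                )
                assert dec.fractions[f"c{j}"] == pytest.approx(oracle, rel=1e-9)
            assert dec.combined == pytest.approx(sum(dec.fractions), rel=1e-12)

    def test_single_covariate_is_squared_correlation(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(0, 1, n)
        idx = [f"s{i}" for i in range(n)]
        table = cov.CovariateTable(pd.DataFrame({"x": x}, index=idx))
        dec = cov.variance_decomposition(
            cov.fit_full_model(pd.Series(y, index=idx, name="t"), table)
        )
        assert dec.fractions["x"] == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, rel=1e-9)

    def test_noise_covariate_null_expectation(self, rng):
        # E[fraction] of an independent covariate is ~1/(n-1)
        n = 200
        y = rng.normal(size=n)
        idx = [f"s{i}" for i in range(n)]
        fracs = []
        for _ in range(100):
            table = cov.CovariateTable(
                pd.DataFrame({"noise": rng.normal(size=n)}, index=idx)
            )
            dec = cov.variance_decomposition(
                cov.fit_full_model(pd.Series(y, index=idx, name="t"), table)
            )
            fracs.append(dec.fractions["noise"])
        assert np.mean(fracs) == pytest.approx(1 / (n - 1), rel=0.35)

    def test_fractions_sum_below_one(self, simple_table, rng):
        y = pd.Series(
            simple_table.data["age"] * 0.01 + rng.normal(size=500),
            index=simple_table.data.index,
            name="t",
        )
        dec = cov.variance_decomposition(cov.fit_full_model(y, simple_table))
        assert (dec.fractions >= 0).all()
        assert 0 <= dec.combined <= 1
        assert dec.combined == pytest.approx(dec.fractions.sum(), rel=1e-9)


class TestRankInverseNormal:
    def test_four_distinct_values_closed_form(self):
        z = cov.rank_inverse_normal(np.array([10.0, 1.0, 5.0, 7.0]))
        expect = stats.norm.ppf([0.875, 0.125, 0.375, 0.625])
        np.testing.assert_allclose(z, expect, atol=1e-12)

    def test_monotone_transform_invariance(self, simple_table, rng):
        y = pd.Series(
            rng.normal(size=500) + 0.02 * simple_table.data["age"],
            index=simple_table.data.index,
            name="t",
        )
        a = cov.adjust_and_rint(y, simple_table, [])
        b = cov.adjust_and_rint(np.exp(y / 3).rename("t"), simple_table, [])
        # affine/monotone transforms change nothing after ranking
        c = cov.adjust_and_rint((5 * y + 2).rename("t"), simple_table, [])
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)
        np.testing.assert_allclose(a.values, c.values, atol=1e-12)

    def test_moments(self, simple_table, rng):
        y = pd.Series(rng.exponential(size=500), index=simple_table.data.index, name="t")
        adj = cov.adjust_and_rint(y, simple_table, ["age"])
        v = adj.values.dropna()
        assert abs(v.mean()) < 1e-10
        assert v.var() == pytest.approx(1.0, abs=0.05)

    def test_residualization_removes_covariate(self, simple_table, rng):
        age = simple_table.data["age"]
        y = pd.Series(0.5 * age + rng.normal(size=500), index=age.index, name="t")
        adj = cov.adjust_and_rint(y, simple_table, ["age"])
        rho = stats.spearmanr(adj.values, age).statistic
        assert abs(rho) < 0.1

    def test_constant_residuals_rejected(self, simple_table):
        y = pd.Series(1.0, index=simple_table.data.index, name="t")
        with pytest.raises(ValueError):
            cov.adjust_and_rint(y, simple_table, [])


class TestCorrelatePairs:
    def test_identical_vectors_reported(self, rng):
        v = rng.normal(size=100)
        panel = pd.DataFrame([v, v], index=["a", "b"])
        out = cov.correlate_pairs(panel)
        assert len(out) == 1
        assert out.loc[0, "r2"] == pytest.approx(1.0)

    def test_independent_pairs_not_reported(self, rng):
        panel = pd.DataFrame(rng.normal(size=(4, 500)), index=list("abcd"))
        out = cov.correlate_pairs(panel, r2_min=0.5)
        assert out.empty

    def test_shared_factor_loading_recovered(self, rng):
        n = 2000
        f = rng.normal(size=n)
        lam = 0.8
        a = lam * f + np.sqrt(1 - lam**2) * rng.normal(size=n)
        b = lam * f + np.sqrt(1 - lam**2) * rng.normal(size=n)
        panel = pd.DataFrame([a, b], index=["a", "b"])
        out = cov.correlate_pairs(panel, r2_min=0.0)
        # Pearson correlation of the pair is lam^2; Spearman close for Gaussians
        assert out.loc[0, "r2"] == pytest.approx((lam**2) ** 2, abs=0.05)

    def test_sparse_overlap_skipped(self, rng):
        a = pd.Series(rng.normal(size=10))
        b = pd.Series([np.nan] * 8 + [1.0, 2.0])
        panel = pd.DataFrame({"x": a, "y": b}).T
        out = cov.correlate_pairs(panel, r2_min=0.0)
        assert out.empty

    def test_categorical_covariate_expansion(self):
        df = pd.DataFrame(
            {"abo": ["A", "B", "O", "AB", "O"]}, index=[f"s{i}" for i in range(5)]
        )
        table = cov.CovariateTable(df)
        design, blocks = table.design()
        # alphabetical levels: A (reference), AB, B, O
        assert blocks["abo"] == ["abo[AB]", "abo[B]", "abo[O]"]
        assert design.loc["s1", "abo[B]"] == 1.0
        assert design.loc["s0"].sum() == 0.0
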