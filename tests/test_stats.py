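"""PCA composite, normality gate, and semipartial correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import tempseg as ts
from tempseg.stats import OUTCOME_COLUMNS, READING_COLUMNS


class TestZTransform:
    def test_unit_spaced_triplet(self):
        np.testing.assert_allclose(ts.z_transform([1, 2, 3]), [-1, 0, 1])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            ts.z_transform([5, 5, 5])

    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        z = ts.z_transform(rng.lognormal(size=40))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)


class TestPcaComposite:
    def test_equicorrelation_closed_form(self):
        # 3x3 equicorrelation with r = 0.65: lambda_1 = 1 + 2r = 2.30 -> 76.7%
        rng = np.random.default_rng(1)
        n = 200_000
        f = rng.standard_normal(n)
        lam = np.sqrt(0.65)
        x = np.column_stack(
            [lam * f + np.sqrt(1 - 0.65) * rng.standard_normal(n) for _ in range(3)]
        )
        pca = ts.pca_composite(x)
        assert pca.eigenvalues[0] == pytest.approx(2.30, abs=0.01)
        assert pca.pct_variance_pc1 == pytest.approx(76.67, abs=0.4)
        assert round(pca.pct_variance_pc1) == 77

    def test_independent_columns(self):
        rng = np.random.default_rng(2)
        pca = ts.pca_composite(rng.standard_normal((100_000, 3)))
        np.testing.assert_allclose(pca.eigenvalues, np.ones(3), atol=0.02)
        assert pca.pct_variance_pc1 == pytest.approx(33.3, abs=1.0)

    def test_eigenvalues_sum_to_three(self):
        rng = np.random.default_rng(3)
        pca = ts.pca_composite(rng.standard_normal((38, 3)) + rng.standard_normal((38, 1)))
        assert pca.eigenvalues.sum() == pytest.approx(3.0, abs=1e-10)

    def test_scores_zero_mean_and_column_order_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((38, 3)) + 2 * rng.standard_normal((38, 1))
        a = ts.pca_composite(x)
        b = ts.pca_composite(x[:, [2, 0, 1]])
        assert abs(a.scores.mean()) < 1e-10
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-10)
        assert np.all(a.loadings > 0)

    def test_constant_column_rejected(self):
        x = np.column_stack([np.ones(38), np.arange(38.0), np.arange(38.0) ** 2])
        with pytest.raises(ValueError):
            ts.pca_composite(x)


class TestVarianceExplained:
    @pytest.mark.parametrize(
        "ev,n,expected", [(2.30, 3, 76.67), (3.0, 3, 100.0), (0.49, 3, 16.33)]
    )
    def test_values(self, ev, n, expected):
        assert ts.variance_explained(ev, n) == pytest.approx(expected, abs=0.01)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ts.variance_explained(3.5, 3)


class TestNormalityGate:
    def test_size_of_test_on_normal_samples(self):
        rng = np.random.default_rng(5)
        parametric = sum(
            ts.normality_gate(rng.standard_normal(38))[0] == "parametric"
            for _ in range(200)
        )
        assert parametric >= 180  # rejection rate ~ alpha = 0.05

    def test_power_on_lognormal_samples(self):
        rng = np.random.default_rng(6)
        rank = sum(
            ts.normality_gate(rng.lognormal(sigma=1.0, size=38))[0] == "rank"
            for _ in range(100)
        )
        assert rank >= 95

    def test_alpha_zero_always_parametric(self):
        rng = np.random.default_rng(7)
        method, _ = ts.normality_gate(rng.lognormal(sigma=1.0, size=38), alpha=0.0)
        assert method == "parametric"


class TestSemipartial:
    def test_orthogonal_covariates_reduce_to_plain_correlation(self):
        rng = np.random.default_rng(8)
        n = 200
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        cov -= cov.mean(axis=0)
        # orthogonalize centered covariates against centered x exactly
        xc = x - x.mean()
        for j in range(2):
            cov[:, j] -= xc * (cov[:, j] @ xc) / (xc @ xc)
        r_semi, _ = ts.semipartial(x, y, cov, "pearson")
        r_plain = np.corrcoef(x - x.mean(), y)[0, 1]
        assert r_semi == pytest.approx(r_plain, abs=1e-12)

    def test_predictor_explained_by_covariates_flags_zero(self):
        n = 30
        rng = np.random.default_rng(9)
        cov = rng.standard_normal((n, 2))
        x = 2.0 * cov[:, 0] - cov[:, 1] + 3.0
        r, p = ts.semipartial(x, rng.standard_normal(n), cov, "pearson")
        assert r == 0.0 and p == 1.0

    def test_six_row_table_against_brute_force(self):
        # independent two-step computation: explicit OLS then correlation
        x = np.array([3.1, 4.5, 2.2, 5.0, 3.8, 4.1])
        y = np.array([10.0, 14.2, 9.1, 16.3, 12.0, 13.5])
        g = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        q = np.array([99.0, 104.0, 95.0, 110.0, 101.0, 103.0])
        cov = np.column_stack([g, q])

        X = np.column_stack([np.ones(6), g, q])
        beta = np.linalg.solve(X.T @ X, X.T @ x)
        resid = x - X @ beta
        r_oracle = np.corrcoef(resid, y)[0, 1]
        df = 6 - 2 - 2
        t_oracle = r_oracle * np.sqrt(df / (1 - r_oracle**2))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), df)

        r, p = ts.semipartial(x, y, cov, "pearson")
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        n = 38
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(n),
                "y": rng.standard_normal(n),
                "c1": rng.standard_normal(n),
                "c2": rng.standard_normal(n),
            }
        )
        df["y"] += 0.6 * df["x"]
        ours, _ = ts.semipartial(df["x"], df["y"], df[["c1", "c2"]].to_numpy())
        ref = pingouin.partial_corr(
            df, x="x", y="y", x_covar=["c1", "c2"], method="pearson"
        )["r"].iloc[0]
        assert ours == pytest.approx(float(ref), abs=1e-6)

    def test_spearman_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(11)
        n = 38
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        r1, p1 = ts.semipartial(x, y, cov, "spearman")
        r2, p2 = ts.semipartial(
            np.exp(x), y**3, np.column_stack([cov[:, 0], np.arctan(cov[:, 1])]),
            "spearman",
        )
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_covariates_equal_plain_correlation(self):
        rng = np.random.default_rng(12)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        r, _ = ts.semipartial(x, y, None, "pearson")
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_rank_deficient_covariates_rejected(self):
        n = 20
        rng = np.random.default_rng(13)
        c = rng.standard_normal(n)
        with pytest.raises(ValueError):
            ts.semipartial(
                rng.standard_normal(n),
                rng.standard_normal(n),
                np.column_stack([c, 2 * c]),
            )

    def test_type_one_error_rate_under_null(self):
        # x, y independent given nothing: rejection rate at alpha=.05 ~ 5%
        rng = np.random.default_rng(14)
        n, reps, alpha = 38, 1000, 0.05
        rejects = 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            cov = rng.standard_normal((n, 2))
            _, p = ts.semipartial(x, y, cov, "pearson")
            rejects += p < alpha
        rate = rejects / reps
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)


class TestAnalyzeCohort:
    def test_report_shape_contract(self, paper_config):
        table = ts.generate_cohort(paper_config, 0)
        report, pca = ts.analyze_cohort(table)
        assert len(report) == 10  # 8 composite-outcome rows + 2 IQ rows
        assert (report["predictor"] == "reading_composite").sum() == 8
        assert (report["predictor"] == "nonverbal_iq").sum() == 2
        assert set(report.loc[report["predictor"] == "reading_composite", "outcome"]) \
            == set(OUTCOME_COLUMNS)
        assert report["coefficient"].abs().max() <= 1.0
        assert pca.eigenvalues.sum() == pytest.approx(3.0, abs=1e-10)

    def test_gate_selects_method_consistently(self, paper_config):
        table = ts.generate_cohort(paper_config, 1)
        report, _ = ts.analyze_cohort(table)
        for _, row in report.iterrows():
            expected = "spearman" if row["normality_p"] < 0.05 else "pearson"
            assert row["method"] == expected

    def test_null_generator_recovers_zero(self):
        from tempseg.cohort import null_config

        cfg = null_config()
        acc = {c: [] for c in OUTCOME_COLUMNS}
        for seed in range(200):
            report, _ = ts.analyze_cohort(ts.generate_cohort(cfg, seed))
            sub = report[report["predictor"] == "reading_composite"]
            for _, row in sub.iterrows():
                acc[row["outcome"]].append(row["coefficient"])
        for col, vals in acc.items():
            assert abs(np.mean(vals)) < 0.02, col

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            ts.analyze_cohort(pd.DataFrame({"gender": [0, 1, 0, 1]}))
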