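"""Predictor prep, spatial GLS, modified t-test, group comparisons."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import divfacets as dv


class TestLGMAnomaly:
    def test_identical_layers_zero(self):
        cur = np.array([1.0, 2.0, 3.0])
        assert dv.lgm_anomaly(cur, [cur, cur, cur]).max() == 0.0

    def test_hand_arithmetic(self):
        cur = np.array([10.0])
        out = dv.lgm_anomaly(cur, [np.array([8.0]), np.array([7.0]),
                                   np.array([6.0])])
        assert out[0] == pytest.approx(3.0)

    def test_random_layers_match_elementwise_recomputation(self):
        rng = np.random.default_rng(0)
        cur = rng.normal(size=50)
        layers = [rng.normal(size=50) for _ in range(3)]
        got = dv.lgm_anomaly(cur, layers)
        expect = (np.abs(cur - layers[0]) + np.abs(cur - layers[1])
                  + np.abs(cur - layers[2])) / 3.0
        np.testing.assert_allclose(got, expect)

    def test_mismatched_layer_errors(self):
        with pytest.raises(ValueError):
            dv.lgm_anomaly(np.zeros(5), [np.zeros(5), np.zeros(4)])


class TestStandardize:
    def test_simple_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out, params = dv.standardize(df)
        np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])
        assert params.loc["a", "mean"] == 2.0

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(3, 2, (40, 3)), columns=list("abc"))
        once, _ = dv.standardize(df)
        twice, _ = dv.standardize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(),
                                   atol=1e-12)
        assert np.abs(once.mean().to_numpy()).max() < 1e-10
        assert np.abs(once.std(ddof=1).to_numpy() - 1).max() < 1e-10

    def test_constant_column_errors(self):
        with pytest.raises(ValueError, match="constant"):
            dv.standardize(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))


class TestCollinearityScreen:
    def test_orthogonal_predictors_retained_with_unit_vif(self):
        df = pd.DataFrame({"a": [-3.0, -1.0, 1.0, 3.0],
                           "b": [1.0, -1.0, -1.0, 1.0]})
        kept, log = dv.collinearity_screen(df)
        assert kept == ["a", "b"] and log == []
        np.testing.assert_allclose(dv.vif(df).to_numpy(), 1.0, atol=1e-10)

    def test_exact_duplicate_dropped_pairwise(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=30)
        df = pd.DataFrame({"a": a, "dup": a.copy(), "b": rng.normal(size=30)})
        kept, log = dv.collinearity_screen(df)
        assert "b" in kept
        assert len([c for c in kept if c in ("a", "dup")]) == 1
        assert log[0]["stage"] == "pairwise"
        assert log[0]["statistic"] == pytest.approx(1.0)

    def test_constant_variable_errors(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0],
                           "b": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="a"):
            dv.collinearity_screen(df)

    def test_planted_collinear_triple_matches_greedy_oracle(self):
        """Six variables with one near-collinear triple: retained set equals
        a brute-force greedy re-derivation; VIFs match statsmodels-backed
        auxiliary regressions."""
        rng = np.random.default_rng(3)
        n = 200
        x1, x2, x3 = (rng.normal(size=n) for _ in range(3))
        df = pd.DataFrame({
            "x1": x1, "x2": x2, "x3": x3,
            "c1": x1 + 0.05 * rng.normal(size=n),
            "c2": x1 + x2 + 0.05 * rng.normal(size=n),
            "x4": rng.normal(size=n),
        })
        kept, log = dv.collinearity_screen(df, r_max=0.7, vif_max=5.0)

        # independent greedy oracle with the same rule
        import statsmodels.api as sm

        def oracle(cols):
            cols = list(cols)
            while True:
                corr = df[cols].corr().abs()
                np.fill_diagonal(corr.values, 0)
                pair = corr.stack().idxmax()
                if corr.loc[pair] < 0.7:
                    break
                a, b = pair
                if len(cols) > 2:
                    ma = corr.loc[a].drop([a, b]).mean()
                    mb = corr.loc[b].drop([a, b]).mean()
                else:
                    ma = mb = 0
                if ma > mb:
                    cols.remove(a)
                elif mb > ma:
                    cols.remove(b)
                else:
                    cols.remove(a if cols.index(a) > cols.index(b) else b)
            while len(cols) >= 2:
                vifs = {}
                for c in cols:
                    X = sm.add_constant(df[[k for k in cols if k != c]])
                    r2 = sm.OLS(df[c], X).fit().rsquared
                    vifs[c] = 1.0 / (1.0 - r2)
                worst = max(vifs, key=vifs.get)
                if vifs[worst] < 5.0:
                    break
                cols.remove(worst)
            return cols

        assert kept == oracle(df.columns)
        # VIFs of the retained set match 1/(1-R^2) from statsmodels
        for c in kept:
            X = sm.add_constant(df[[k for k in kept if k != c]])
            r2 = sm.OLS(df[c], X).fit().rsquared
            assert dv.vif(df[kept])[c] == pytest.approx(1.0 / (1.0 - r2))


def _grid_coords(n_rows, n_cols):
    return np.array([(i, j) for i in range(n_rows) for j in range(n_cols)],
                    dtype=float)


class TestExponentialGLS:
    def test_uncorrelated_data_matches_ols_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n = 100
        coords = rng.uniform(0, 100, (n, 2))
        X = rng.standard_normal((n, 2))
        y = 1.0 + X @ np.array([0.5, -0.25]) + rng.standard_normal(n)
        res = dv.ExponentialGLS(y, X, coords).fit()
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(res.params.to_numpy(), ols.params,
                                   atol=1e-6)

    def test_noise_free_linear_recovery(self):
        rng = np.random.default_rng(8)
        coords = _grid_coords(8, 8)
        X = rng.standard_normal((64, 2))
        y = 3.0 + X @ np.array([2.0, -1.0])
        res = dv.ExponentialGLS(y, X, coords).fit()
        np.testing.assert_allclose(
            res.params.to_numpy(), [3.0, 2.0, -1.0], atol=1e-8
        )
        assert res.sigma2 < 1e-12

    def test_parameter_recovery_short_simulation(self):
        """Mini parameter-recovery run (the fuller version is part of the
        acceptance checks): mean beta-hat near truth, rho-hat in range."""
        coords = _grid_coords(15, 15)
        D = squareform(pdist(coords))
        L = np.linalg.cholesky(np.exp(-D / 3.0) + 1e-10 * np.eye(225))
        betas, rhos = [], []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((225, 2))
            y = X @ np.array([2.0, -1.0]) + L @ rng.standard_normal(225)
            res = dv.ExponentialGLS(y, X, coords).fit()
            betas.append(res.params.to_numpy()[1:])
            rhos.append(res.rho)
        mean_beta = np.mean(betas, axis=0)
        assert mean_beta[0] == pytest.approx(2.0, abs=0.15)
        assert mean_beta[1] == pytest.approx(-1.0, abs=0.15)
        assert 1.5 <= np.median(rhos) <= 6.0

    def test_singular_design_errors(self):
        coords = _grid_coords(5, 5)
        x = np.arange(25, dtype=float)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="singular"):
            dv.ExponentialGLS(np.arange(25, dtype=float), X, coords)

    def test_summary_contains_fit_info(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, (30, 2))
        res = dv.ExponentialGLS(
            rng.standard_normal(30), rng.standard_normal((30, 1)), coords
        ).fit()
        text = res.summary()
        assert "rho" in text and "REML" in text and "x0" in text

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_nlme_reference(self, tmp_path):
        """Estimates, SEs and range match nlme::gls with corExp (REML)."""
        rng = np.random.default_rng(4)
        n = 80
        coords = rng.uniform(0, 20, (n, 2))
        D = squareform(pdist(coords))
        L = np.linalg.cholesky(np.exp(-D / 4.0) + 1e-10 * np.eye(n))
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        y = 1.5 + 2.0 * x1 - 1.0 * x2 + L @ rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2,
                           "px": coords[:, 0], "py": coords[:, 1]})
        df.to_csv(tmp_path / "d.csv", index=False)
        script = textwrap.dedent("""
            suppressMessages(library(nlme))
            d <- read.csv(commandArgs(TRUE)[1])
            m <- gls(y ~ x1 + x2, data = d,
                     correlation = corExp(form = ~px + py), method = "REML")
            tt <- summary(m)$tTable
            rng <- coef(m$modelStruct$corStruct, unconstrained = FALSE)
            write.csv(rbind(tt, c(rng, NA, NA, NA)), commandArgs(TRUE)[2])
        """)
        (tmp_path / "gls.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "gls.R"), str(tmp_path / "d.csv"),
             str(tmp_path / "out.csv")],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        res = dv.ExponentialGLS(y, df[["x1", "x2"]], coords).fit()
        np.testing.assert_allclose(
            res.params.to_numpy(), ref["Value"].to_numpy()[:3], rtol=1e-4
        )
        np.testing.assert_allclose(
            res.bse.to_numpy(), ref["Std.Error"].to_numpy()[:3], rtol=1e-3
        )
        assert res.rho == pytest.approx(ref["Value"].to_numpy()[3], rel=1e-2)


class TestModifiedTTest:
    def test_white_noise_effective_n_near_n(self):
        coords = _grid_coords(20, 20)
        neffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mc = dv.modified_ttest(rng.standard_normal(400),
                                   rng.standard_normal(400), coords)
            neffs.append(mc.n_eff)
        assert np.mean(neffs) > 0.9 * 400

    def test_zero_autocorrelation_reduces_to_classical(self):
        """When every estimated class autocorrelation is zero, n_eff = n and
        t/p equal the classical test."""
        from divfacets import spatial as sp

        coords = _grid_coords(5, 6)
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(30), rng.standard_normal(30)
        orig = sp._class_correlogram
        sp._class_correlogram = lambda z, masks: np.zeros(len(masks))
        try:
            mc = dv.modified_ttest(a, b, coords)
        finally:
            sp._class_correlogram = orig
        r, p = stats.pearsonr(a, b)
        assert mc.n_eff == pytest.approx(30)
        assert mc.p == pytest.approx(p, rel=1e-10)

    def test_autocorrelated_fields_shrink_effective_n(self):
        from scipy.ndimage import gaussian_filter

        coords = _grid_coords(20, 20)
        rng = np.random.default_rng(1)
        a = gaussian_filter(rng.standard_normal((20, 20)), 2.0).ravel()
        b = gaussian_filter(rng.standard_normal((20, 20)), 2.0).ravel()
        mc = dv.modified_ttest(a, b, coords)
        assert mc.n_eff < 0.5 * 400

    def test_degenerate_perfect_correlation_errors(self):
        coords = _grid_coords(4, 5)
        a = np.arange(20, dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            dv.modified_ttest(a, a * 2 + 1, coords)


class TestGroupCompare:
    def test_h_matches_rank_sum_formula(self):
        """Three clean groups vs the textbook H computed by hand."""
        values = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        gc = dv.group_compare(values, groups)
        # brute-force formula: no ties
        N = 9
        ranks = stats.rankdata(values)
        H = 12.0 / (N * (N + 1)) * sum(
            3 * (ranks[groups == g].mean()) ** 2 for g in "abc"
        ) - 3 * (N + 1)
        assert gc.h == pytest.approx(H)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=30)
        groups = np.repeat(["g1", "g2", "g3"], 10)
        a = dv.group_compare(values, groups)
        b = dv.group_compare(np.exp(values), groups)
        assert a.h == pytest.approx(b.h)
        np.testing.assert_allclose(a.dunn["z"], b.dunn["z"])

    def test_null_groups_rarely_significant(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            values = rng.normal(size=36)
            groups = np.repeat(["a", "b", "c"], 12)
            if dv.group_compare(values, groups).p < 0.05:
                rejections += 1
        assert rejections <= 10

    def test_separated_groups_get_distinct_letters(self):
        values = np.array([1, 2, 3, 4, 50, 51, 52, 53, 100, 101, 102, 103],
                          dtype=float)
        groups = np.repeat(["lo", "mid", "hi"], 4)
        gc = dv.group_compare(values, groups)
        # Dunn with Holm at n=4 per group may not fully separate all pairs,
        # but the extreme groups must not share a letter
        assert set(gc.letters["lo"]).isdisjoint(set(gc.letters["hi"]))

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            dv.group_compare(np.arange(4.0), np.array(["a", "a", "a", "b"]))

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=40)
        values[:10] += 3.0
        groups = np.repeat(["a", "b", "c", "d"], 10)
        gc = dv.group_compare(values, groups)
        assert (gc.dunn["p_adj"] >= gc.dunn["p"] - 1e-15).all()
        assert (gc.dunn["p_adj"] <= 1.0).all()
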