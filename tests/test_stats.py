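"""DODS GLM, smoothness, cluster correction, partial correlation, Z-scores."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import sficd
from sficd.stats import _ols_contrast


def two_group_frame(n_per=6, seed=0, covs=0):
    rng = np.random.default_rng(seed)
    d = {"group": np.repeat([0, 1], n_per)}
    for k in range(covs):
        d[f"c{k}"] = rng.standard_normal(2 * n_per)
    return pd.DataFrame(d)


class TestDesign:
    def test_two_groups_no_covariates(self):
        X = sficd.build_dods_design(two_group_frame())
        assert X.X.shape[1] == 2
        assert X.contrasts["group_offset"].tolist() == [-1.0, 1.0]

    def test_dods_doubles_columns_per_covariate(self):
        X = sficd.build_dods_design(two_group_frame(covs=1), covariates=("c0",))
        assert X.X.shape[1] == 4
        assert X.rank == 4

    def test_median_split(self):
        assert sficd.median_split([10, 12, 18, 30]).tolist() == [0, 0, 1, 1]

    def test_moderator_enters_as_per_group_slope_with_contrast(self):
        df = two_group_frame(n_per=6)
        df["hcy"] = [10, 11, 12, 20, 21, 22] * 2
        X = sficd.build_dods_design(df, moderator="hcy")
        assert X.X.shape[1] == 4
        assert "interaction" in X.contrasts
        assert X.contrasts["interaction"][-2:].tolist() == [-1.0, 1.0]

    def test_rank_deficiency_names_columns(self):
        df = two_group_frame(covs=1)
        df["dup"] = df["c0"]
        with pytest.raises(ValueError, match="collinear"):
            sficd.build_dods_design(df, covariates=("c0", "dup"))

    def test_single_group_rejected(self):
        df = pd.DataFrame({"group": [0, 0, 0]})
        with pytest.raises(ValueError):
            sficd.build_dods_design(df)


class TestGLM:
    def test_equals_pooled_two_sample_t(self):
        rng = np.random.default_rng(1)
        n = 24
        Y = rng.standard_normal((n, 40))
        g = np.repeat([0, 1], n // 2)
        X = sficd.build_dods_design(pd.DataFrame({"group": g}))
        res = sficd.fit_glm_vertexwise(Y, X, "group_offset")
        t_ref = sps.ttest_ind(Y[g == 1], Y[g == 0]).statistic
        assert np.abs(res.t - t_ref).max() < 1e-10
        assert np.all(res.df == n - 2)

    def test_matches_normal_equations_oracle(self):
        """Random n=12 design with covariates vs explicit (X'X)^-1 X'y."""
        rng = np.random.default_rng(2)
        df = two_group_frame(n_per=6, seed=2, covs=2)
        X = sficd.build_dods_design(df, covariates=("c0", "c1"))
        Y = rng.standard_normal((12, 5))
        c = X.contrasts["group_offset"]
        res = sficd.fit_glm_vertexwise(Y, X, c)
        A = X.X
        xtx_inv = np.linalg.inv(A.T @ A)
        for v in range(5):
            beta = xtx_inv @ A.T @ Y[:, v]
            resid = Y[:, v] - A @ beta
            df_ = 12 - A.shape[1]
            s2 = resid @ resid / df_
            t_ref = (c @ beta) / np.sqrt(s2 * c @ xtx_inv @ c)
            assert res.effect[v] == pytest.approx(c @ beta, abs=1e-8)
            assert res.t[v] == pytest.approx(t_ref, abs=1e-8)

    def test_null_p_values_uniform(self):
        """Under pure noise the vertexwise p map is uniform (KS p > 0.01)."""
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((16, 2000))
        X = sficd.build_dods_design(two_group_frame(n_per=8))
        res = sficd.fit_glm_vertexwise(Y, X, "group_offset")
        assert sps.kstest(res.p, "uniform").pvalue > 0.01

    def test_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(4)
        df = two_group_frame(n_per=10, seed=4, covs=2)
        Y = rng.standard_normal((20, 10))
        X1 = sficd.build_dods_design(df, covariates=("c0", "c1"))
        df2 = df.copy()
        df2["c0"] = df2["c0"] * 1e5 + 300.0
        df2["c1"] = df2["c1"] * 1e-4 - 2.0
        X2 = sficd.build_dods_design(df2, covariates=("c0", "c1"))
        r1 = sficd.fit_glm_vertexwise(Y, X1, "group_offset")
        r2 = sficd.fit_glm_vertexwise(Y, X2, "group_offset")
        assert np.abs(r1.t - r2.t).max() < 1e-8

    def test_missing_vertices_dropped_with_adjusted_df(self):
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((20, 6))
        Y[3, 2] = np.nan
        Y[4, 2] = np.nan
        X = sficd.build_dods_design(two_group_frame(n_per=10))
        res = sficd.fit_glm_vertexwise(Y, X, "group_offset")
        assert res.df[2] == 16 and res.df[0] == 18
        sub = np.delete(Y[:, 2], [3, 4])
        g = np.delete(np.repeat([0, 1], 10), [3, 4])
        t_ref = sps.ttest_ind(sub[g == 1], sub[g == 0]).statistic
        assert res.t[2] == pytest.approx(t_ref, abs=1e-10)

    def test_df_nonpositive_rejected(self):
        X = sficd.build_dods_design(pd.DataFrame({"group": [0, 1]}))
        with pytest.raises(ValueError):
            _ols_contrast(np.zeros((2, 3)), X.X, X.contrasts["group_offset"])


class TestSmoothnessEstimate:
    def test_white_noise_clamps_to_edge_length(self, stats_mesh):
        rng = np.random.default_rng(0)
        R = rng.standard_normal((6, stats_mesh.n_vertices))
        est = sficd.estimate_smoothness(R, stats_mesh)
        assert est <= 2.0 * stats_mesh.edge_lengths.mean()

    def test_self_consistent_with_smoother(self, sheet40):
        """Noise smoothed to 15 mm re-estimates to 15 mm within 15%."""
        rng = np.random.default_rng(1)
        W = sficd.smoothing_operator(sheet40, 15.0)
        sm = (W @ rng.standard_normal((sheet40.n_vertices, 8))).T
        assert sficd.estimate_smoothness(sm, sheet40) == pytest.approx(15.0,
                                                                       rel=0.15)

    def test_constant_residuals_rejected(self, tiny_mesh):
        with pytest.raises(ValueError):
            sficd.estimate_smoothness(np.ones((4, tiny_mesh.n_vertices)),
                                      tiny_mesh)


class TestClusterCorrection:
    def null_result(self, mesh, seed=0, n=20):
        spec = sficd.CohortSpec(mesh=mesh, n_per_group=n, noise_sd=0.05,
                                noise_fwhm=6.0, rng_seed=seed)
        maps, dtab = sficd.generate_cohort_maps(spec)
        X = sficd.build_dods_design(dtab, covariates=("age", "sex",
                                                      "education", "tiv"))
        return sficd.fit_glm_vertexwise(maps["t0"], X, "group_offset")

    def test_zero_stat_map_has_no_clusters(self, stats_mesh):
        nv = stats_mesh.n_vertices
        res = sficd.VertexStatResult(effect=np.zeros(nv), t=np.zeros(nv),
                                     p=np.ones(nv), df=np.full(nv, 10.0),
                                     residuals=np.random.default_rng(0)
                                     .standard_normal((12, nv)))
        rep = sficd.cluster_correct_montecarlo(res, stats_mesh, n_iter=200,
                                               fwhm=6.0, rng_seed=1)
        assert rep.clusters == []

    def test_p_floor_is_one_over_niter_plus_one(self, stats_mesh):
        res = self.null_result(stats_mesh, seed=11)
        # force one huge artificial cluster by inflating t in a disc
        d = np.linalg.norm(stats_mesh.vertices[:, :2] - 19.5, axis=1)
        res.t[d < 15] = 50.0
        res.p[d < 15] = 1e-30
        rep = sficd.cluster_correct_montecarlo(res, stats_mesh, n_iter=200,
                                               fwhm=6.0, rng_seed=2)
        assert rep.clusters[0].p_corrected == pytest.approx(1.0 / 201.0)

    def test_p_monotone_in_area(self, stats_mesh):
        res = self.null_result(stats_mesh, seed=12)
        rep = sficd.cluster_correct_montecarlo(res, stats_mesh, n_iter=300,
                                               fwhm=6.0, rng_seed=3)
        areas = [c.area_mm2 for c in rep.clusters]
        ps = [c.p_corrected for c in rep.clusters]
        order = np.argsort(areas)
        assert np.all(np.diff(np.array(ps)[order]) <= 1e-12)

    def test_signed_clusters_do_not_mix(self, stats_mesh):
        res = self.null_result(stats_mesh, seed=13)
        rep = sficd.cluster_correct_montecarlo(res, stats_mesh, n_iter=200,
                                               fwhm=6.0, rng_seed=4)
        for c in rep.clusters:
            assert np.all(np.sign(res.t[c.vertices]) == c.sign)


class TestLongitudinal:
    def test_rate_arithmetic(self):
        r = sficd.longitudinal_rate(np.array([1.0]), np.array([2.0]), 27.0)
        assert r[0] == pytest.approx(1 / 27)

    def test_identical_maps_zero_rate(self):
        m = np.random.default_rng(0).random(30)
        assert np.allclose(sficd.longitudinal_rate(m, m, 12.0), 0.0)

    def test_missing_propagates_and_bad_months_rejected(self):
        a = np.array([1.0, np.nan])
        r = sficd.longitudinal_rate(a, np.array([2.0, 2.0]), 10.0)
        assert np.isnan(r[1]) and r[0] == pytest.approx(0.1)
        with pytest.raises(ValueError):
            sficd.longitudinal_rate(a, a, 0.0)

    def test_one_sample_t_matches_oracle(self):
        rng = np.random.default_rng(6)
        R = rng.standard_normal((15, 25)) * 0.3
        res = sficd.within_group_rate_test(R)
        t_ref = sps.ttest_1samp(R, 0.0).statistic
        assert np.abs(res.t - t_ref).max() < 1e-10

    def test_zero_variance_vertices_flagged(self):
        R = np.random.default_rng(7).standard_normal((8, 5))
        R[:, 3] = 0.4  # constant nonzero rate
        res = sficd.within_group_rate_test(R)
        assert np.isnan(res.t[3]) and not np.isnan(res.t[0])

    def test_injected_rate_detected_in_region(self, stats_mesh):
        """Cohort rate effect yields a significant cluster over the region."""
        d = np.linalg.norm(stats_mesh.vertices[:, :2] - 19.5, axis=1)
        region = d <= 8
        rate = np.where(region, 0.004, 0.0)
        wins = 0
        for seed in range(10):
            spec = sficd.CohortSpec(mesh=stats_mesh, n_per_group=15,
                                    noise_sd=0.05, noise_fwhm=6.0,
                                    rate_map=rate, rng_seed=seed)
            maps, _ = sficd.generate_cohort_maps(spec)
            rates = sficd.longitudinal_rate(maps["t0"], maps["t1"], 27.0)
            res = sficd.within_group_rate_test(rates)
            rep = sficd.cluster_correct_montecarlo(res, stats_mesh,
                                                   n_iter=500, rng_seed=seed)
            wins += any(region[c.vertices].any() for c in rep.significant)
        assert wins >= 9


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self):
        rng = np.random.default_rng(8)
        x, y = rng.standard_normal((2, 40))
        r, p = sficd.partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_perfect_dependence(self):
        x = np.linspace(0, 1, 20)
        r, p = sficd.partial_correlation(x, x.copy())
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(9)
        n, k = 30, 4
        C = rng.standard_normal((n, k))
        x = C @ rng.standard_normal(k) + rng.standard_normal(n)
        y = 0.4 * x + C @ rng.standard_normal(k) + rng.standard_normal(n)
        r, p = sficd.partial_correlation(x, y, C)
        Z = np.column_stack([np.ones(n), C])
        H = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
        rx, ry = x - H @ x, y - H @ y
        r_ref = rx @ ry / np.sqrt((rx @ rx) * (ry @ ry))
        t_ref = r_ref * np.sqrt((n - 2 - k) / (1 - r_ref ** 2))
        p_ref = 2 * sps.t.sf(abs(t_ref), n - 2 - k)
        assert r == pytest.approx(r_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        n = 25
        C = rng.standard_normal((n, 2))
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        r, p = sficd.partial_correlation(x, y, C)
        df = pd.DataFrame(np.column_stack([x, y, C]),
                          columns=["x", "y", "c1", "c2"])
        ref = pg.partial_corr(df, "x", "y", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)

    def test_constant_residuals_rejected(self):
        c = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            sficd.partial_correlation(2 * c + 1, np.random.default_rng(0).random(10),
                                      c[:, None])


class TestCompositeZScores:
    MEANS = {"COWAT": 30.0, "CFT": 15.0, "SRT": 300.0, "CRT": 500.0,
             "CPAL": 40.0, "ISLT": 20.0}
    SDS = {"COWAT": 5.0, "CFT": 3.0, "SRT": 40.0, "CRT": 60.0,
           "CPAL": 8.0, "ISLT": 4.0}

    def test_baseline_mean_gives_zero_and_one_sd_gives_one(self):
        scores = pd.DataFrame([self.MEANS,
                               {k: v + self.SDS[k] for k, v in self.MEANS.items()}])
        z = sficd.composite_zscores(scores, self.MEANS, self.SDS)
        assert np.allclose(z.iloc[0][[f"Z_{k}" for k in self.MEANS]], 0.0)
        assert np.allclose(z.iloc[1][[f"Z_{k}" for k in self.MEANS]], 1.0)

    def test_domain_composites_are_means_of_pairs(self):
        row = dict(self.MEANS)
        row["COWAT"] = self.MEANS["COWAT"] + self.SDS["COWAT"]  # Z=1, CFT Z=0
        z = sficd.composite_zscores(pd.DataFrame([row]), self.MEANS, self.SDS)
        assert z["executive"].iloc[0] == pytest.approx(0.5)
        assert z["psychomotor"].iloc[0] == pytest.approx(0.0)
        assert z["memory"].iloc[0] == pytest.approx(0.0)

    def test_zero_sd_rejected(self):
        sds = dict(self.SDS, COWAT=0.0)
        with pytest.raises(ValueError):
            sficd.composite_zscores(pd.DataFrame([self.MEANS]), self.MEANS, sds)
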