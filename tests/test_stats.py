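import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from lvmcm.stats import (bray_curtis, centralities, distinctness,
                         extinction_timing_stats, fit_models,
                         variance_partition)


class TestBrayCurtis:
    def test_identity(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_direct_substitution(self):
        assert bray_curtis([1, 0], [1, 2]) == pytest.approx(0.5)

    def test_undefined_for_double_zero(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 100), min_size=2, max_size=8),
           st.lists(st.floats(0, 100), min_size=2, max_size=8))
    def test_symmetric_and_bounded(self, x, y):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        if (x + y).sum() == 0:
            return
        bc = bray_curtis(x, y)
        assert 0.0 <= bc <= 1.0
        assert bc == pytest.approx(bray_curtis(y, x))
        if bc == 0.0:
            np.testing.assert_allclose(x, y, atol=1e-12)


class TestDistinctness:
    def test_identical_sites_all_zero(self):
        b = np.tile([[1.0], [2.0]], (1, 4))
        np.testing.assert_allclose(distinctness(b), 0.0)

    def test_fully_distinct_site(self):
        b = np.array([[1.0, 1.0, 0.0],
                      [0.0, 0.0, 2.0]])
        beta = distinctness(b)
        assert beta[2] == pytest.approx(1.0)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0, 1, size=(6, 3))
        beta = distinctness(b)
        for x in range(3):
            manual = np.mean([bray_curtis(b[:, x], b[:, y])
                              for y in range(3) if y != x])
            assert beta[x] == pytest.approx(manual)

    def test_needs_two_sites(self):
        with pytest.raises(ValueError):
            distinctness(np.ones((3, 1)))


class TestCentralities:
    def test_star_hub_maximal_everywhere(self):
        n = 5
        adj = np.zeros((n, n), dtype=int)
        adj[0, 1:] = adj[1:, 0] = 1
        c = centralities(adj)
        for col in ("degree", "closeness", "betweenness", "eigenvector"):
            assert c[col][0] == c[col].max()
            assert (c[col][1:] < c[col][0]).all()

    def test_cycle_is_vertex_transitive(self):
        n = 6
        adj = np.zeros((n, n), dtype=int)
        for i in range(n):
            adj[i, (i + 1) % n] = adj[(i + 1) % n, i] = 1
        c = centralities(adj)
        for col in c.columns:
            np.testing.assert_allclose(c[col], c[col][0], atol=1e-9)

    def test_path_middle_betweenness(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        c = centralities(adj)
        assert c["betweenness"][1] == pytest.approx(1.0)
        assert c["betweenness"][0] == 0.0

    def test_eigenvector_normalised_to_max_one(self):
        adj = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]])
        c = centralities(adj)
        assert c["eigenvector"].max() == pytest.approx(1.0)


def synthetic_table(rng, n=150, coef_area=0.0, coef_dist=0.5, noise=0.05):
    x = rng.standard_normal((n, 6))
    df = pd.DataFrame(x, columns=["biomass_fraction", "distinctness", "degree",
                                  "closeness", "betweenness", "eigenvector"])
    df["value"] = (coef_area * df["biomass_fraction"]
                   + coef_dist * df["distinctness"]
                   + noise * rng.standard_normal(n))
    return df


class TestFitModels:
    def test_recovers_planted_single_predictor(self):
        # the true predictor is always selected and its standardised
        # coefficient recovered; spurious extras may ride along (AIC admits
        # a noise predictor whenever its chi-square exceeds the penalty 2)
        rng = np.random.default_rng(0)
        df = synthetic_table(rng, coef_area=0.0, coef_dist=0.6, noise=0.02)
        report = fit_models(df)
        assert "distinctness" in report.selected
        assert report.coefficients["distinctness"] == pytest.approx(0.6, abs=0.05)
        assert report.spearman["distinctness"] > 0.9
        assert report.adj_r2_distinctness > report.adj_r2_area

    def test_null_response_selection_matches_chi_square_oracle(self):
        # under a pure-noise response, a given spurious predictor joins the
        # min-AIC subset iff its chi-square improvement exceeds the AIC
        # penalty of 2 (asymptotically): P = P(chi2_1 > 2) = 0.157, and the
        # intercept-only model wins with P = (1 - 0.157)^6 = 0.358
        from scipy.stats import chi2
        p_in = chi2.sf(2.0, df=1)
        rng = np.random.default_rng(1)
        draws = 400
        intercept_wins = 0
        area_in = 0
        for _ in range(draws):
            df = synthetic_table(rng, n=120, coef_area=0, coef_dist=0, noise=1.0)
            sel = fit_models(df).selected
            intercept_wins += sel == ()
            area_in += "biomass_fraction" in sel
        se = np.sqrt(p_in * (1 - p_in) / draws)
        assert abs(area_in / draws - p_in) < 4 * se
        p_none = (1 - p_in) ** 6
        se_none = np.sqrt(p_none * (1 - p_none) / draws)
        assert abs(intercept_wins / draws - p_none) < 4 * se_none

    def test_partition_identity_exact(self):
        rng = np.random.default_rng(2)
        df = synthetic_table(rng, coef_area=0.3, coef_dist=0.4, noise=0.3)
        p = variance_partition(df)
        total = p["unique_area"] + p["unique_distinctness"] + p["shared"]
        assert total == pytest.approx(p["r2_full"], abs=1e-10)

    def test_selection_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(3)
        df = synthetic_table(rng, coef_area=0.4, coef_dist=0.5, noise=0.1)
        scaled = df.copy()
        scaled["biomass_fraction"] = scaled["biomass_fraction"] * 1e3 + 7.0
        scaled["degree"] = scaled["degree"] * 0.01 - 2.0
        assert fit_models(df).selected == fit_models(scaled).selected

    def test_constant_predictor_dropped(self):
        rng = np.random.default_rng(4)
        df = synthetic_table(rng)
        df["degree"] = 3.0
        report = fit_models(df)
        assert "degree" not in report.selected

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            fit_models(synthetic_table(rng, n=5))


def test_spearman_invariant_under_monotone_transform():
    rng = np.random.default_rng(6)
    x = rng.uniform(0.1, 2.0, 80)
    y = x ** 2 + rng.normal(0, 0.1, 80)
    base = spearmanr(x, y).statistic
    assert spearmanr(np.log(x), y).statistic == pytest.approx(base)
    assert spearmanr(x, np.exp(y)).statistic == pytest.approx(base)


class TestExtinctionTiming:
    def test_constant_distance(self):
        rec = pd.DataFrame({"time": [1.0, 10.0, 40.0],
                            "distance_frac": [0.05, 0.05, 0.05]})
        s = extinction_timing_stats(rec)
        assert s["mean_distance_leq50"] == pytest.approx(0.05)
        assert np.isnan(s["mean_distance_gt50"])

    def test_lag_strata_count_all_records(self):
        rng = np.random.default_rng(7)
        rec = pd.DataFrame({"time": rng.uniform(0, 300, 100),
                            "distance_frac": rng.uniform(0, 1, 100)})
        s = extinction_timing_stats(rec)
        assert s["n_leq50"] + s["n_gt50"] == 100
        assert s["n_gt120"] <= s["n_gt50"]
        assert len(s["cumulative_times"]) == 100
        assert s["cumulative_fraction"][-1] == 1.0

    def test_uniform_random_sites_match_mean_pair_distance(self):
        # Monte-Carlo oracle: last-detection sites drawn uniformly over the
        # box give a mean distance near the uniform-square expectation
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 1, (20000, 2))
        b = rng.uniform(0, 1, (20000, 2))
        dists = np.linalg.norm(a - b, axis=1)
        rec = pd.DataFrame({"time": np.full(20000, 100.0),
                            "distance_frac": dists})
        s = extinction_timing_stats(rec)
        assert s["mean_distance_gt50"] == pytest.approx(0.5214, abs=0.01)

    def test_empty_records(self):
        assert extinction_timing_stats(pd.DataFrame(
            columns=["time", "distance_frac"]))["n"] == 0
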