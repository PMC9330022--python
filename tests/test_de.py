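import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plastisweep.de import (
    ComparisonResult,
    DEThresholds,
    DegThresholds,
    bh_adjust,
    call_dems,
    cpm,
    deg_ttest,
    estimate_common_dispersion,
    exact_test_pvalue,
    nb_exact_test,
    qc_correlation,
    qc_pca,
    tmm_factors,
)
from plastisweep.design import make_design

from conftest import toy_count_matrix


# ---------------------------------------------------------------------------
# TMM


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([10, 20, 5, 40, 100, 3, 7, 55, 12, 9])
        df = pd.DataFrame({"s1": col, "s2": col})
        f = tmm_factors(df)
        np.testing.assert_allclose(f.values, [1.0, 1.0], atol=1e-12)

    def test_geometric_mean_is_one(self, small_counts):
        cm, _ = small_counts
        f = tmm_factors(cm)
        assert abs(np.exp(np.log(f.values).mean()) - 1.0) < 1e-8

    def test_two_sample_toy_matches_sort_based_oracle(self):
        # column 2 = 3x column 1 except two strongly spiked features; the
        # oracle trims M and A values via explicit argsort slicing.
        rng = np.random.default_rng(0)
        col1 = rng.integers(50, 500, size=20).astype(float)
        col2 = col1 * 3.0
        col2[:2] *= 25.0  # spiked features the trim should discard
        df = pd.DataFrame({"s1": col1.astype(int), "s2": col2.astype(int)})

        obs, ref = df["s2"].values.astype(float), df["s1"].values.astype(float)
        No, Nr = obs.sum(), ref.sum()
        m = np.log2((obs / No) / (ref / Nr))
        a = 0.5 * np.log2((obs / No) * (ref / Nr))
        n = len(m)
        lo_m, lo_a = int(np.floor(0.3 * n)), int(np.floor(0.05 * n))
        keep_m = set(np.argsort(m, kind="stable")[lo_m : n - lo_m])
        keep_a = set(np.argsort(a, kind="stable")[lo_a : n - lo_a])
        keep = sorted(keep_m & keep_a)
        w = 1.0 / ((No - obs[keep]) / (No * obs[keep]) + (Nr - ref[keep]) / (Nr * ref[keep]))
        f_oracle = 2.0 ** (np.sum(w * m[keep]) / np.sum(w))

        f = tmm_factors(df, ref_sample="s1")
        expected = np.array([f_oracle**-0.5, f_oracle**0.5])  # geomean-rescaled
        np.testing.assert_allclose(f.values, expected, rtol=1e-10)

    def test_all_zero_sample_is_named(self):
        df = pd.DataFrame({"good": [1, 2, 3], "bad": [0, 0, 0]})
        with pytest.raises(ValueError, match="bad"):
            tmm_factors(df)

    def test_recovers_planted_library_sizes(self, null_counts):
        # on effect-free data the effective library sizes should be
        # proportional to the planted ones within 5%
        cm, truth = null_counts
        f = tmm_factors(cm)
        eff = cm.counts.sum(axis=0) * f
        ratio = (eff / truth.lib_sizes).values
        ratio /= ratio.mean()
        assert np.abs(ratio - 1).max() < 0.05


# ---------------------------------------------------------------------------
# CPM


class TestCPM:
    def test_single_feature_entire_library(self):
        df = pd.DataFrame({"s1": [500], "s2": [100]})
        out = cpm(df)
        np.testing.assert_allclose(out.values, [[1e6, 1e6]])

    def test_zero_count_linear_is_zero(self):
        df = pd.DataFrame({"s1": [0, 10], "s2": [5, 5]})
        assert cpm(df).iloc[0, 0] == 0.0

    def test_toy_matches_hand_arithmetic(self):
        df = pd.DataFrame({"s1": [10, 30, 60], "s2": [5, 5, 40]})
        out = cpm(df)
        expected = np.array(
            [[10 / 100, 5 / 50], [30 / 100, 5 / 50], [60 / 100, 40 / 50]]
        ) * 1e6
        np.testing.assert_allclose(out.values, expected)

    def test_log_variant_uses_scaled_prior(self):
        df = pd.DataFrame({"s1": [10, 90], "s2": [20, 180]})
        out = cpm(df, log=True, prior_count=2.0)
        lib = np.array([100.0, 200.0])
        prior = 2.0 * lib / lib.mean()
        expected = np.log2((df.values + prior) / (lib + 2 * prior) * 1e6)
        np.testing.assert_allclose(out.values, expected)

    def test_mismatched_factors_rejected(self):
        df = pd.DataFrame({"s1": [1, 2], "s2": [3, 4]})
        bad = pd.Series([1.0, 1.0], index=["s1", "other"])
        with pytest.raises(ValueError, match="different sample"):
            cpm(df, bad)


# ---------------------------------------------------------------------------
# dispersion


class TestCommonDispersion:
    def test_poisson_counts_give_small_phi(self):
        rng = np.random.default_rng(1)
        mu = rng.uniform(50, 500, size=500)
        counts = pd.DataFrame(
            rng.poisson(mu[:, None], size=(500, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        groups = ["a"] * 3 + ["b"] * 3
        assert estimate_common_dispersion(counts, groups) < 0.05

    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(2)
        phi = 0.2
        mu = rng.uniform(50, 500, size=500)
        r = 1 / phi
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu[:, None]), size=(500, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        est = estimate_common_dispersion(counts, ["a"] * 3 + ["b"] * 3)
        assert 0.1 <= est <= 0.35

    def test_identical_replicates_give_zero(self):
        col = np.array([10, 200, 30, 55])
        counts = pd.DataFrame({"s1": col, "s2": col, "s3": col, "s4": col})
        est = estimate_common_dispersion(counts, ["a", "a", "b", "b"])
        assert est < 1e-4

    def test_no_replication_warns_and_returns_zero(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [3, 4]})
        with pytest.warns(UserWarning):
            assert estimate_common_dispersion(counts, ["a", "b"]) == 0.0


# ---------------------------------------------------------------------------
# exact test


def _binom_doubled_tail(k: int, t: int, p: float) -> float:
    lower = stats.binom.cdf(k, t, p)
    upper = stats.binom.sf(k - 1, t, p)
    return min(1.0, 2.0 * min(lower, upper))


class TestExactTest:
    def test_symmetric_split_gives_p1_and_logfc0(self, liver_design):
        counts = np.tile(np.array([[7], [40], [123]]), (1, 12))
        cm = toy_count_matrix(counts, liver_design)
        res = nb_exact_test(cm, "TC", "LC", phi=0.1)
        np.testing.assert_allclose(res.table["log2fc"].values, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.table["pvalue"].values, 1.0)

    @pytest.mark.parametrize("t", range(1, 51))
    def test_poisson_limit_matches_binomial_oracle(self, t):
        # 1v1 samples, equal library sizes, phi=0: the conditional split
        # is Binomial(t, 1/2); agreement to 1e-10 on every split
        for k in range(t + 1):
            mine = exact_test_pvalue(k, t - k, 1, 1, phi=0.0)
            oracle = _binom_doubled_tail(k, t, 0.5)
            assert mine == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("mu", [1.3, 8.0])
    def test_tiny_case_matches_nb_convolution_oracle(self, mu):
        # total=10, 2v2, phi=0.1: enumerate all 11 splits; the oracle
        # conditions a scipy nbinom group-sum pmf on the total, and the
        # answer must not depend on the nuisance mean mu.
        phi, n, t = 0.1, 2, 10
        r = n / phi  # group sum of 2 iid NB(1/phi, p) is NB(2/phi, p)
        p_nb = (1 / phi) / (1 / phi + mu)
        pmf = stats.nbinom.pmf(np.arange(t + 1), r, p_nb)
        cond = pmf * pmf[::-1]
        cond /= cond.sum()
        for ka in range(t + 1):
            lower, upper = cond[: ka + 1].sum(), cond[ka:].sum()
            oracle = min(1.0, 2.0 * min(lower, upper))
            assert exact_test_pvalue(ka, t - ka, n, n, phi) == pytest.approx(oracle, abs=1e-10)

    def test_negative_phi_rejected(self, small_counts):
        cm, _ = small_counts
        with pytest.raises(ValueError):
            nb_exact_test(cm, "TC", "LC", phi=-0.1)

    def test_overlapping_groups_rejected(self, small_counts):
        cm, _ = small_counts
        tc = cm.samples_of_group("TC")
        with pytest.raises(ValueError, match="disjoint"):
            nb_exact_test(cm, tc, tc, phi=0.1)


# ---------------------------------------------------------------------------
# BH


class TestBH:
    def test_single_pvalue_identity(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_hand_computed_example(self):
        # p*n/rank = [.04, .04, .04, .04] after the monotone cap
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_order_preserved_under_permutation(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        perm = rng.permutation(40)
        adj_perm = bh_adjust(p[perm])
        np.testing.assert_allclose(adj_perm, adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


# ---------------------------------------------------------------------------
# DEM calling


def _result_row(log2fc, log2cpm, pvalue):
    table = pd.DataFrame(
        {"log2fc": [log2fc], "log2cpm": [log2cpm], "pvalue": [pvalue],
         "fdr": [np.nan], "de": [False], "direction": ["NONE"]},
        index=["feat"],
    )
    return ComparisonResult("A-B", "A", "B", table)


class TestCallDems:
    def test_boundary_log2cpm_strictly_greater(self):
        res = call_dems(_result_row(1.5, 2.0, 0.05))
        assert not res.table["de"].iloc[0]

    def test_inclusive_fc_and_fdr_boundaries(self):
        res = call_dems(_result_row(1.5, 2.1, 0.05))
        assert res.table["de"].iloc[0]
        assert res.table["direction"].iloc[0] == "UP_IN_A"

    def test_down_regulation_direction(self):
        res = call_dems(_result_row(-1.8, 3.0, 0.001))
        assert res.table["direction"].iloc[0] == "UP_IN_B"
        assert res.de_set() == {"feat": -1}

    def test_empty_result_gives_empty_set(self):
        table = pd.DataFrame(
            columns=["log2fc", "log2cpm", "pvalue", "fdr", "de", "direction"]
        )
        res = call_dems(ComparisonResult("A-B", "A", "B", table))
        assert res.de_set() == {}


# ---------------------------------------------------------------------------
# DEG t-test


class TestDegTtest:
    def test_identical_groups_empty(self):
        expr = pd.DataFrame(
            np.tile([[3.0], [5.0]], (1, 6)), columns=[f"s{i}" for i in range(6)]
        )
        expr += np.random.default_rng(4).normal(0, 0.1, expr.shape)
        out = deg_ttest(expr, ["s0", "s1", "s2"], ["s0", "s1", "s2"].copy())
        assert not out["de"].any()

    def test_perfect_separation_called(self):
        expr = pd.DataFrame(
            [[3.0, 3.0, 3.0, 0.0, 0.0, 0.0]], columns=[f"s{i}" for i in range(6)]
        )
        out = deg_ttest(expr, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert out["de"].iloc[0]
        assert out["fc"].iloc[0] == pytest.approx(8.0)

    def test_too_few_replicates_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="replicates"):
            deg_ttest(expr, ["a"], ["b", "c"])


# ---------------------------------------------------------------------------
# QC


class TestQC:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        corr = qc_correlation(expr)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)
        np.testing.assert_allclose(corr.values, corr.values.T)

    def test_affine_copy_correlates_perfectly(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        expr = pd.DataFrame({"a": x, "b": 2 * x + 3})
        assert qc_correlation(expr).loc["a", "b"] == pytest.approx(1.0)

    def test_constant_sample_reported_missing(self):
        expr = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        corr = qc_correlation(expr)
        assert np.isnan(corr.loc["a", "b"])

    def test_three_sample_toy_matches_covariance_formula(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        corr = qc_correlation(expr)
        for s1 in expr.columns:
            for s2 in expr.columns:
                x, y = expr[s1].values, expr[s2].values
                expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                    np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
                )
                assert corr.loc[s1, s2] == pytest.approx(expected, abs=1e-12)

    def test_duplicated_samples_have_identical_scores(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(25, 3))
        expr = pd.DataFrame(
            np.column_stack([x, x[:, 0]]), columns=["a", "b", "c", "a2"]
        )
        scores, frac = qc_pca(expr, n_components=2)
        np.testing.assert_allclose(scores.loc["a"].values, scores.loc["a2"].values,
                                   atol=1e-10)
        assert (np.diff(frac) <= 1e-12).all()

    def test_variance_fractions_match_eigendecomposition(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(size=(4, 3)), columns=["a", "b", "c"])
        _, frac = qc_pca(expr, n_components=2)
        xc = expr.values.T - expr.values.T.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(xc @ xc.T))[::-1]
        expected = eig / eig.sum()
        np.testing.assert_allclose(frac, expected[:2], atol=1e-10)

    def test_too_many_components_rejected(self):
        expr = pd.DataFrame(np.ones((5, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="n_components"):
            qc_pca(expr, n_components=3)


class TestThresholdValidation:
    def test_de_thresholds(self):
        with pytest.raises(ValueError):
            DEThresholds(max_fdr=1.5).validate()

    def test_deg_thresholds(self):
        with pytest.raises(ValueError):
            DegThresholds(min_fc=0.5).validate()
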