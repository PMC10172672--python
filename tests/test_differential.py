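import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from metaomix.differential import (
    bh_adjust,
    count_de_test,
    dm_test,
    filter_tissue_bias_probes,
    fit_variance_prior,
    m_transform,
    mirna_de,
    quantile_normalize,
    scale_normalize_counts,
)
from metaomix.synthetic_cohort import nb_sample


def bh_bruteforce(p):
    """Independent step-up oracle written from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        out[i] = running
    return out


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42]) == pytest.approx([0.42])

    def test_matches_bruteforce_and_statsmodels(self, rng):
        p = rng.uniform(size=1000)
        ours = bh_adjust(p)
        assert np.allclose(ours, bh_bruteforce(list(p)))
        assert np.allclose(ours, multipletests(p, method="fdr_bh")[1])

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    def test_bounds_and_rank_monotonicity(self, rng):
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert ((adj >= 0) & (adj <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestQuantileNormalize:
    def test_rank_mean_construction(self):
        df = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        assert np.allclose(out["s1"], [2.5, 3.5, 4.5])
        assert np.allclose(out["s2"], [2.5, 3.5, 4.5])

    def test_identical_columns_are_fixed_point(self):
        df = pd.DataFrame({"s1": [3.0, 1.0, 2.0], "s2": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_sorted_columns_identical_after_normalization(self, rng):
        df = pd.DataFrame(rng.uniform(size=(100, 5)))
        out = quantile_normalize(df).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.uniform(size=(50, 4)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_single_sample_is_error(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"s1": [1.0, 2.0]}))


class TestScaleNormalize:
    def test_pure_depth_difference(self, rng):
        base = rng.lognormal(4, 1, 2000)
        counts = pd.DataFrame({
            "a": np.round(base * 500).astype(int),
            "b": np.round(base * 1000).astype(int),
        })
        factors, norm = scale_normalize_counts(counts)
        assert np.allclose(factors, 1.0, atol=0.01)
        # library-size scaling alone equalizes the samples (up to rounding)
        assert np.allclose(norm["a"], norm["b"], rtol=1e-3)

    def test_factors_have_unit_geometric_mean(self, rng):
        counts = pd.DataFrame(rng.poisson(100, size=(500, 4)))
        factors, _ = scale_normalize_counts(counts)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-12)

    def test_trimming_resists_spiked_genes(self, rng):
        base = rng.lognormal(4, 1, 2000).round().astype(int) + 1
        spiked = base.copy()
        spiked[:100] *= 100  # 5% of genes massively inflated in one sample
        counts = pd.DataFrame({"ref": base, "spiked": spiked})
        _, norm = scale_normalize_counts(counts)
        # trimming removes the spike, so unspiked genes normalize equally ...
        ratio = (norm["spiked"][100:] / norm["ref"][100:]).median()
        assert abs(np.log2(ratio)) < np.log2(1.05)
        # ... whereas plain library-size scaling (untrimmed oracle) is off ~2x
        lib = counts.sum(axis=0)
        naive = (spiked[100:] / lib["spiked"]) / (base[100:] / lib["ref"])
        assert abs(np.log2(np.median(naive))) > np.log2(1.5)

    def test_all_zero_sample_is_error(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            scale_normalize_counts(counts)


class TestCountDeTest:
    def _matrix(self, rng, n_genes=500, planted=None):
        means = rng.lognormal(np.log(100), 1, n_genes)
        tumor = means.copy()
        if planted:
            tumor[:planted] *= 4
        cols = {f"A{i}": nb_sample(tumor, 0.1, rng) for i in range(4)}
        cols |= {f"B{i}": nb_sample(means, 0.1, rng) for i in range(4)}
        return pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])

    def test_decision_flag_applies_both_thresholds(self, rng):
        df = self._matrix(rng, planted=50)
        res = count_de_test(df, [f"A{i}" for i in range(4)], [f"B{i}" for i in range(4)])
        expected = (res.fdr < 0.01) & (res.logFC.abs() > 1.0)
        assert (res.significant == expected).all()
        assert res.significant.sum() > 0

    def test_all_zero_genes_excluded(self, rng):
        df = self._matrix(rng)
        df.iloc[10] = 0
        res = count_de_test(df, [f"A{i}" for i in range(4)], [f"B{i}" for i in range(4)])
        assert df.index[10] not in res.index
        assert len(res) == len(df) - 1

    def test_planted_genes_recovered_with_correct_sign(self, rng):
        df = self._matrix(rng, planted=50)
        res = count_de_test(df, [f"A{i}" for i in range(4)], [f"B{i}" for i in range(4)])
        planted = [f"g{i}" for i in range(50)]
        sig_planted = res.loc[planted]
        assert (sig_planted.logFC > 1).mean() > 0.9
        assert sig_planted.significant.mean() >= 0.8

    def test_group_too_small_is_error(self, rng):
        df = self._matrix(rng)
        with pytest.raises(ValueError):
            count_de_test(df, ["A0"], ["B0", "B1"])

    def test_symmetry_under_group_swap(self, rng):
        df = self._matrix(rng, planted=20)
        a = [f"A{i}" for i in range(4)]
        b = [f"B{i}" for i in range(4)]
        # normalize=False isolates the test's own symmetry (TMM reference
        # selection is column-order dependent)
        res_ab = count_de_test(df, a, b, normalize=False)
        res_ba = count_de_test(df, b, a, normalize=False)
        assert np.allclose(res_ab.logFC, -res_ba.logFC, atol=1e-12)
        # tail sums accumulate in opposite order, so allow float-level slack
        assert np.allclose(res_ab.p_value, res_ba.p_value, rtol=1e-2)


class TestDmTest:
    def test_constant_half_betas_are_null(self):
        df = pd.DataFrame(0.5, index=[f"p{i}" for i in range(20)],
                          columns=[f"s{i}" for i in range(8)])
        res = dm_test(df, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        assert np.allclose(res.delta_beta, 0.0)
        assert np.allclose(res.t, 0.0)
        assert np.allclose(res.p_value, 1.0)

    def test_noise_free_group_difference(self):
        a = pd.DataFrame(0.8, index=["p1"], columns=["a1", "a2", "a3"])
        b = pd.DataFrame(0.2, index=["p1"], columns=["b1", "b2", "b3"])
        df = pd.concat([a, b], axis=1)
        # add null probes so the variance prior is estimable
        rs = np.random.default_rng(0)
        null = pd.DataFrame(np.clip(rs.normal(0.5, 0.03, (50, 6)), 0.01, 0.99),
                            index=[f"n{i}" for i in range(50)], columns=df.columns)
        res = dm_test(pd.concat([df, null]), ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert res.loc["p1", "delta_beta"] == pytest.approx(0.6)
        assert res.loc["p1", "direction"] == "hyper"

    def test_planted_probes_detected(self, rng):
        n_null, n_dm = 2000, 100
        base = rng.uniform(0.35, 0.65, n_null + n_dm)
        mean_a = base.copy()
        mean_a[:n_dm] -= 0.3
        cols = {}
        for i in range(8):
            cols[f"a{i}"] = np.clip(mean_a + rng.normal(0, 0.03, base.size), 0.01, 0.99)
        for i in range(8):
            cols[f"b{i}"] = np.clip(base + rng.normal(0, 0.03, base.size), 0.01, 0.99)
        df = pd.DataFrame(cols, index=[f"p{i}" for i in range(base.size)])
        res = dm_test(df, [f"a{i}" for i in range(8)], [f"b{i}" for i in range(8)])
        planted = res.iloc[:n_dm]
        assert planted.significant.mean() >= 0.95
        assert (planted.direction == "hypo").all()
        fp = res.iloc[n_dm:].significant.sum()
        assert fp / max(1, res.significant.sum()) <= 0.02

    def test_whole_group_missing_probe_dropped(self):
        rs = np.random.default_rng(1)
        df = pd.DataFrame(np.clip(rs.normal(0.5, 0.05, (30, 6)), 0, 1),
                          index=[f"p{i}" for i in range(30)],
                          columns=[f"s{i}" for i in range(6)])
        df.loc["p0", ["s0", "s1", "s2"]] = np.nan
        res = dm_test(df, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert "p0" not in res.index

    def test_m_transform_inverts_logistic_map(self, rng):
        beta = rng.uniform(0.01, 0.99, 100)
        m = m_transform(beta, epsilon=1e-3)
        back = 2.0 ** m / (1.0 + 2.0 ** m)
        assert np.allclose(back, beta, atol=1e-12)

    def test_variance_prior_posterior_between_extremes(self, rng):
        s2 = rng.chisquare(6, 500) / 6 * 0.09
        d0, s0_sq = fit_variance_prior(s2, df=6)
        post = (d0 * s0_sq + 6 * s2) / (d0 + 6)
        lo = np.minimum(s2, s0_sq)
        hi = np.maximum(s2, s0_sq)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()


class TestTissueBiasFilter:
    def test_clear_marker_dropped_equal_kept(self):
        liver = pd.DataFrame({"l1": [0.9, 0.5], "l2": [0.9, 0.5]}, index=["p1", "p2"])
        colon = pd.DataFrame({"c1": [0.1, 0.5], "c2": [0.1, 0.5]}, index=["p1", "p2"])
        keep = filter_tissue_bias_probes(liver, colon)
        assert not keep["p1"] and keep["p2"]

    def test_no_shared_probes_is_error(self):
        liver = pd.DataFrame({"l1": [0.9]}, index=["p1"])
        colon = pd.DataFrame({"c1": [0.1]}, index=["q1"])
        with pytest.raises(ValueError):
            filter_tissue_bias_probes(liver, colon)

    def test_planted_bias_probes_all_removed(self, small_cohort):
        cohort, truth = small_cohort
        betas = cohort.betas.values
        keep = filter_tissue_bias_probes(
            betas[cohort.sample_ids("adjacent_liver")],
            betas[cohort.sample_ids("control_colon")],
        )
        assert not keep[sorted(truth.bias_probes)].any()
        unbiased = keep.index.difference(truth.bias_probes)
        assert (~keep[unbiased]).mean() <= 0.01


class TestMirnaDe:
    def test_threshold_rule_and_no_lfc_gate(self, small_cohort):
        cohort, _ = small_cohort
        res = mirna_de(
            cohort.mirna_counts.values,
            cohort.sample_ids("metastasis"),
            cohort.sample_ids("adjacent_liver"),
        )
        assert (res.significant == (res.fdr < 0.05)).all()

    def test_planted_mirnas_detected_with_sign(self, small_cohort):
        cohort, truth = small_cohort
        res = mirna_de(
            cohort.mirna_counts.values,
            cohort.sample_ids("metastasis"),
            cohort.sample_ids("adjacent_liver"),
        )
        hits = 0
        for m, lfc in truth.de_mirnas.items():
            if res.loc[m, "significant"] and np.sign(res.loc[m, "logFC"]) == np.sign(lfc):
                hits += 1
        assert hits / len(truth.de_mirnas) >= 0.9

    def test_identical_groups_yield_no_calls(self, rng):
        means = rng.lognormal(np.log(200), 1, 300)
        cols = {f"x{i}": nb_sample(means, 0.1, rng) for i in range(10)}
        df = pd.DataFrame(cols, index=[f"m{i}" for i in range(300)])
        res = mirna_de(df, [f"x{i}" for i in range(5)], [f"x{i}" for i in range(5, 10)])
        assert res.significant.sum() <= 2
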