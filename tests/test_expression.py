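import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from helpnet import expression, synthetic_data
from helpnet.data_model import (
    CtRecord,
    DegenerateInputError,
    ExpressionMatrix,
    TFBMMatrix,
    ValidationError,
)


def small_expression(tpm, groups=None, sexes=None, offset=1.0):
    tpm = np.atleast_2d(np.asarray(tpm, dtype=float))
    g, m = tpm.shape
    groups = groups or ["opener"] * (m // 2) + ["nonopener"] * (m - m // 2)
    sexes = sexes or (["male", "female"] * m)[:m]
    return ExpressionMatrix(
        abundance=tpm,
        gene_ids=[f"G{j}" for j in range(g)],
        sample_ids=[f"s{i}" for i in range(m)],
        group=np.asarray(groups, dtype=object),
        sex=np.asarray(sexes, dtype=object),
        log_offset=offset,
    )


class TestFitDegModel:
    def test_constant_gene_has_unit_fold_change(self):
        e = small_expression([[5.0] * 8])
        d = expression.fit_deg_model(e)
        assert d.beta_group[0] == pytest.approx(0.0, abs=1e-12)
        assert d.fold_change[0] == pytest.approx(1.0)

    def test_constructed_26_fold_gene(self):
        # every opener TPM exactly 2.6x the nonopener value, balanced sexes,
        # tiny offset so the log2 transform is effectively exact
        base = 1000.0
        tpm = [[base * 2.6] * 4 + [base] * 4]
        e = small_expression(
            tpm,
            groups=["opener"] * 4 + ["nonopener"] * 4,
            sexes=["male", "male", "female", "female"] * 2,
            offset=1e-9,
        )
        d = expression.fit_deg_model(e)
        assert d.fold_change[0] == pytest.approx(2.6, abs=1e-6)

    def test_betas_match_normal_equations(self):
        rng = np.random.default_rng(0)
        tpm = rng.uniform(1, 1000, size=(20, 12))
        e = small_expression(
            tpm,
            groups=["opener"] * 6 + ["nonopener"] * 6,
            sexes=["male", "female"] * 6,
        )
        d = expression.fit_deg_model(e)
        X = d.design
        Y = np.log2(tpm + 1.0)
        beta_ref = np.linalg.solve(X.T @ X, X.T @ Y.T).T
        assert np.allclose(d.beta_group, beta_ref[:, 1], atol=1e-10)
        # t statistics against statsmodels-style pieces
        resid = Y - beta_ref @ X.T
        sigma2 = (resid**2).sum(axis=1) / (12 - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert np.allclose(d.t_stat, beta_ref[:, 1] / se, atol=1e-10)

    def test_confounded_design_rejected(self):
        tpm = np.ones((3, 8))
        with pytest.raises(expression.CollinearDesignError, match="confound"):
            expression.fit_deg_model(
                small_expression(
                    tpm,
                    groups=["opener"] * 4 + ["nonopener"] * 4,
                    sexes=["male"] * 4 + ["female"] * 4,
                )
            )

    def test_fold_change_consistency(self):
        rng = np.random.default_rng(1)
        e = small_expression(rng.uniform(1, 100, size=(10, 8)))
        d = expression.fit_deg_model(e)
        assert np.allclose(d.fold_change, np.exp2(d.beta_group), atol=1e-12)


class TestSelectDegs:
    def test_unit_fold_changes_give_empty_lists(self):
        e = small_expression(np.ones((5, 8)) * 7)
        d = expression.fit_deg_model(e)
        up, down, counts = expression.select_degs(d)
        assert up == [] and down == [] and counts["total"] == 0

    def test_boundary_gene_is_inclusive(self):
        d = expression.fit_deg_model(small_expression(np.ones((3, 8))))
        d.beta_group = np.array([np.log2(1.5), -np.log2(1.5), 0.0])
        up, down, _ = expression.select_degs(d)
        assert up == ["G0"] and down == ["G1"]

    def test_planted_counts_recovered(self):
        ups, downs = [], []
        for seed in range(20):
            e, _, truth = synthetic_data.gen_expression(
                g_genes=500,
                n_up=50,
                n_down=30,
                deg_log2_effect=1.0,
                sigma=0.25,
                seed=seed,
            )
            d = expression.fit_deg_model(e)
            _, _, counts = expression.select_degs(d)
            ups.append(counts["up"])
            downs.append(counts["down"])
        assert abs(np.mean(ups) - 50) <= 5
        assert abs(np.mean(downs) - 30) <= 3

    def test_threshold_at_or_below_one_rejected(self):
        d = expression.fit_deg_model(small_expression(np.ones((2, 8))))
        with pytest.raises(ValueError):
            expression.select_degs(d, threshold=1.0)


class TestTfbmStatistic:
    @staticmethod
    def tiny_tfbm(counts):
        counts = np.asarray(counts, dtype=float)
        return TFBMMatrix(
            counts=counts,
            gene_ids=[f"G{j}" for j in range(counts.shape[0])],
            motif_ids=[f"M{j}" for j in range(counts.shape[1])],
        )

    def test_identical_means_give_zero(self):
        t = self.tiny_tfbm([[2, 1], [4, 3], [2, 1], [4, 3]])
        stat = expression.tfbm_statistic(t, ["G0", "G1"], ["G2", "G3"])
        assert np.allclose(stat, 0.0)

    def test_fourfold_ratio_without_epsilon(self):
        t = self.tiny_tfbm([[4.0], [4.0], [1.0], [1.0]])
        stat = expression.tfbm_statistic(t, ["G0", "G1"], ["G2", "G3"], epsilon=0.0)
        assert stat[0] == pytest.approx(2.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_matches_direct_formula_and_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(2.0, size=(12, 4)).astype(float)
        t = self.tiny_tfbm(counts)
        up = [f"G{j}" for j in range(5)]
        down = [f"G{j}" for j in range(5, 12)]
        stat = expression.tfbm_statistic(t, up, down)
        ref = np.log2(counts[:5].mean(axis=0) + 0.5) - np.log2(
            counts[5:].mean(axis=0) + 0.5
        )
        assert np.allclose(stat, ref, atol=1e-12)
        swapped = expression.tfbm_statistic(t, down, up)
        assert np.allclose(stat, -swapped, atol=1e-12)

    def test_empty_set_rejected(self):
        t = self.tiny_tfbm([[1.0], [2.0]])
        with pytest.raises(ValidationError):
            expression.tfbm_statistic(t, [], ["G0"])


class TestTfbmBootstrap:
    def test_planted_enrichment_detected(self):
        e, t, truth = synthetic_data.gen_expression(g_genes=1000, seed=0)
        d = expression.fit_deg_model(e)
        res = expression.tfbm_bootstrap(e, d, t, n_cycles=200, seed=0)
        for mid in truth.enriched_motifs:
            j = res.motif_ids.index(mid)
            assert res.z[j] > 2 and res.statistic[j] > 0

    def test_null_motifs_near_nominal_rejection(self):
        rejections, n_null = 0, 0
        for seed in range(6):
            e, t, truth = synthetic_data.gen_expression(g_genes=800, seed=seed)
            d = expression.fit_deg_model(e)
            res = expression.tfbm_bootstrap(e, d, t, n_cycles=200, seed=seed)
            for mid, p in zip(res.motif_ids, res.p):
                if mid not in truth.enriched_motifs:
                    n_null += 1
                    rejections += p < 0.05
        # roughly nominal: within a factor ~2 of alpha = 0.05
        assert 0.005 <= rejections / n_null <= 0.12

    def test_same_seed_reproducible(self):
        e, t, _ = synthetic_data.gen_expression(g_genes=300, seed=2)
        d = expression.fit_deg_model(e)
        r1 = expression.tfbm_bootstrap(e, d, t, n_cycles=100, seed=5)
        r2 = expression.tfbm_bootstrap(e, d, t, n_cycles=100, seed=5)
        assert np.array_equal(r1.z, r2.z) and np.array_equal(r1.boot_se, r2.boot_se)

    def test_se_shrinks_with_larger_deg_sets(self):
        # the SE measures gene-sampling noise of the set means, so larger
        # up/down sets must give (stochastically) smaller SEs
        ses = []
        for n_up, n_down in ((25, 15), (100, 60)):
            se_sum = 0.0
            for seed in range(3):
                e, t, _ = synthetic_data.gen_expression(
                    g_genes=600, n_up=n_up, n_down=n_down, seed=seed
                )
                d = expression.fit_deg_model(e)
                res = expression.tfbm_bootstrap(e, d, t, n_cycles=100, seed=seed)
                se_sum += float(np.mean(res.boot_se))
            ses.append(se_sum)
        assert ses[1] < ses[0]

    def test_weak_signal_errors_when_sets_collapse(self):
        # no planted DEGs and tiny noise: up/down sets empty most cycles
        e, t, _ = synthetic_data.gen_expression(
            g_genes=200, n_up=1, n_down=1, deg_log2_effect=0.7, sigma=0.2, seed=3
        )
        d = expression.fit_deg_model(e)
        with pytest.raises((ValidationError, Exception)):
            with pytest.warns(RuntimeWarning):
                expression.tfbm_bootstrap(e, d, t, n_cycles=50, seed=3)


class TestDdct:
    @staticmethod
    def ct_records(delta_cts, groups):
        return [
            CtRecord(f"s{i}", g, ct_target=20.0 + d, ct_reference=20.0)
            for i, (d, g) in enumerate(zip(delta_cts, groups))
        ]

    def test_identical_ct_gives_unit_fold_change(self):
        recs = self.ct_records([3.0] * 6, ["opener"] * 3 + ["nonopener"] * 3)
        res = expression.ddct_fold_change(recs)
        assert np.allclose(res.samples["fold_change"], 1.0)

    def test_one_cycle_doubling(self):
        recs = self.ct_records([3.0, 3.0, 3.0, 2.0], ["nonopener"] * 3 + ["opener"])
        res = expression.ddct_fold_change(recs)
        opener_fc = res.samples.loc[res.samples["group"] == "opener", "fold_change"]
        assert opener_fc.iloc[0] == pytest.approx(2.0)

    def test_reference_geometric_mean_is_one(self):
        rng = np.random.default_rng(4)
        recs = self.ct_records(
            rng.normal(5, 1, size=10), ["nonopener"] * 5 + ["opener"] * 5
        )
        res = expression.ddct_fold_change(recs)
        ref_fc = res.samples.loc[
            res.samples["group"] == "nonopener", "fold_change"
        ].to_numpy()
        assert scipy.stats.gmean(ref_fc) == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_pipeline(self):
        rng = np.random.default_rng(5)
        dcts = rng.normal(4, 0.5, size=8)
        groups = ["nonopener"] * 4 + ["opener"] * 4
        res = expression.ddct_fold_change(self.ct_records(dcts, groups))
        ref_mean = dcts[:4].mean()
        expected = 2.0 ** -(dcts - ref_mean)
        assert np.allclose(res.samples["fold_change"], expected, atol=1e-12)

    def test_target_shift_invariance_of_group_ratio(self):
        rng = np.random.default_rng(6)
        dcts = rng.normal(4, 0.5, size=8)
        groups = ["nonopener"] * 4 + ["opener"] * 4
        r1 = expression.ddct_fold_change(self.ct_records(dcts, groups))
        r2 = expression.ddct_fold_change(self.ct_records(dcts + 1.0, groups))
        g1 = r1.group_summary.set_index("group")["mean_fc"]
        g2 = r2.group_summary.set_index("group")["mean_fc"]
        assert g1["opener"] / g1["nonopener"] == pytest.approx(
            g2["opener"] / g2["nonopener"], rel=1e-12
        )

    def test_missing_reference_group_rejected(self):
        recs = self.ct_records([1.0, 2.0], ["opener", "opener"])
        with pytest.raises(ValidationError):
            expression.ddct_fold_change(recs)


class TestGroupTtest:
    def test_identical_groups(self):
        with pytest.raises(DegenerateInputError):
            expression.group_ttest([1, 1, 1, 1], ["a", "a", "b", "b"])

    def test_five_vs_five_has_eight_df(self):
        rng = np.random.default_rng(7)
        t, df, p = expression.group_ttest(
            rng.normal(size=10), ["opener"] * 5 + ["nonopener"] * 5
        )
        assert df == 8

    def test_matches_pooled_formula(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 4)
        t, df, p = expression.group_ttest(
            np.concatenate([a, b]), ["x"] * 6 + ["y"] * 4
        )
        sp2 = ((5 * a.var(ddof=1)) + (3 * b.var(ddof=1))) / 8
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 6 + 1 / 4))
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert df == 8
        assert p == pytest.approx(2 * scipy.stats.t.sf(abs(t_ref), 8), abs=1e-12)
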