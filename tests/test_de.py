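import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as hst

from mirsig.de import (
    bh_adjust,
    compare_tests,
    de_table,
    paired_t,
    paired_wilcoxon,
    select_signature,
)
from mirsig.simulate import SimulationConfig, generate_paired_dataset
from oracles import bh_step_up, signed_rank_exact_p


class TestPairedT:
    def test_hand_computed_example(self, paired_builder):
        ct, annot = paired_builder([[1.0, 2.0, 3.0]])
        r = paired_t(ct, annot).iloc[0]
        assert r.t_stat == pytest.approx(3.4641016, abs=1e-6)
        assert r.df == 2
        assert r.p_t == pytest.approx(0.0742, abs=2e-4)
        assert r.direction == "-"  # higher Ct in malignant = down-regulated

    def test_label_swap_antisymmetry(self, paired_builder, rng):
        ct, annot = paired_builder(rng.normal(0, 1, size=(6, 8)))
        swapped = annot.copy()
        swapped["tissue_class"] = swapped["tissue_class"].map(
            {"normal": "malignant", "malignant": "normal"}
        )
        a = paired_t(ct, annot)
        b = paired_t(ct, swapped)
        np.testing.assert_allclose(a.t_stat, -b.t_stat)
        np.testing.assert_allclose(a.p_t, b.p_t)
        assert (a.direction != b.direction).all()

    def test_degenerate_and_untestable_flags(self, paired_builder):
        ct, annot = paired_builder([[0.0, 0.0, 0.0], [1.5, 1.5, 1.5]])
        r = paired_t(ct, annot)
        assert r.loc["f1", "flag"] == "untestable" and np.isnan(r.loc["f1", "p_t"])
        assert r.loc["f2", "flag"] == "degenerate" and r.loc["f2", "p_t"] == 0.0
        assert np.isposinf(r.loc["f2", "t_stat"])

    def test_pairs_with_missing_wells_dropped_per_feature(self, paired_builder):
        ct, annot = paired_builder([[1.0, 2.0, 3.0, 4.0]])
        ct.loc["f1", "2M"] = np.nan
        r = paired_t(ct, annot).iloc[0]
        assert r.n_pairs_used == 3
        exp = st.ttest_1samp([1.0, 3.0, 4.0], 0.0)
        assert r.p_t == pytest.approx(exp.pvalue, rel=1e-10)

    def test_matches_one_sample_oracle_on_random_instances(self, paired_builder, rng):
        """Vectorized paired t agrees with scipy's one-sample t on the
        differences to >=10 significant digits, 100 random instances."""
        for _ in range(100):
            n_feat = int(rng.integers(1, 6))
            n_pairs = int(rng.integers(3, 9))
            diffs = rng.normal(0, 1, size=(n_feat, n_pairs))
            ct, annot = paired_builder(diffs)
            res = paired_t(ct, annot)
            for i in range(n_feat):
                exp = st.ttest_1samp(diffs[i], 0.0)
                assert res.t_stat.iloc[i] == pytest.approx(exp.statistic, rel=1e-10)
                assert res.p_t.iloc[i] == pytest.approx(exp.pvalue, rel=1e-10)


class TestPairedWilcoxon:
    def test_three_positive_differences(self, paired_builder):
        ct, annot = paired_builder([[1.0, 2.0, 3.0]])
        assert paired_wilcoxon(ct, annot).iloc[0] == pytest.approx(0.25)

    def test_six_positive_differences(self, paired_builder):
        ct, annot = paired_builder([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        assert paired_wilcoxon(ct, annot).iloc[0] == pytest.approx(2 / 64)

    def test_sign_flip_symmetry(self, paired_builder, rng):
        d = rng.normal(0, 1, size=(4, 7))
        ct1, annot = paired_builder(d)
        ct2, _ = paired_builder(-d)
        p1 = paired_wilcoxon(ct1, annot)
        p2 = paired_wilcoxon(ct2, annot)
        np.testing.assert_allclose(p1, p2)

    def test_matches_enumeration_oracle(self, paired_builder, rng):
        """Exact signed-rank p agrees with full 2^n enumeration on 100
        random tie-free instances."""
        for _ in range(100):
            n = int(rng.integers(4, 11))
            d = rng.normal(0.3, 1, size=(1, n))
            ct, annot = paired_builder(d)
            got = paired_wilcoxon(ct, annot).iloc[0]
            assert got == pytest.approx(signed_rank_exact_p(d[0]), rel=1e-12)

    def test_zero_differences_dropped(self, paired_builder):
        ct, annot = paired_builder([[0.0, 1.0, 2.0, 3.0]])
        # zeros dropped -> same as the n=3 all-positive case
        assert paired_wilcoxon(ct, annot).iloc[0] == pytest.approx(0.25)


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.42])), [0.42])

    def test_matches_step_up_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), bh_step_up(p), rtol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hst.integers(0, 10_000))
    def test_permutation_invariance_and_bounds(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(0, 1, size=20)
        perm = r.permutation(20)
        adj = bh_adjust(p)
        adj_perm = bh_adjust(p[perm])
        np.testing.assert_allclose(adj[perm], adj_perm, rtol=1e-12)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-15)

    def test_missing_p_excluded_from_m(self):
        p = pd.Series([0.01, np.nan, 0.02])
        adj = bh_adjust(p)
        assert np.isnan(adj.iloc[1])
        np.testing.assert_allclose(adj.dropna(), bh_step_up(np.array([0.01, 0.02])))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 1.5]))


class TestSignature:
    def test_recovers_planted_set_and_orders_by_p(self):
        ds = generate_paired_dataset(SimulationConfig(seed=42))
        res = paired_t(ds.ct, ds.annotation)
        sig = select_signature(res, 1e-5)
        assert set(sig.feature_ids) == set(ds.truth_de)
        ps = [res.at[f, "p_t"] for f in sig.feature_ids]
        assert ps == sorted(ps)

    def test_alpha_zero_empty_and_nesting(self):
        ds = generate_paired_dataset(SimulationConfig(seed=3, n_cases=8, n_features=60))
        res = paired_t(ds.ct, ds.annotation)
        assert len(select_signature(res, 0.0)) == 0
        s4 = set(select_signature(res, 1e-4).feature_ids)
        s5 = set(select_signature(res, 1e-5).feature_ids)
        assert s5 <= s4

    def test_planted_up_effects_get_plus_calls(self):
        cfg = SimulationConfig(seed=9, n_cases=12, n_features=40, n_de=4,
                               effect_sign_fraction_up=1.0, noise_sd=0.2)
        ds = generate_paired_dataset(cfg)
        res = paired_t(ds.ct, ds.annotation)
        assert (res.loc[sorted(ds.truth_de), "direction"] == "+").all()

    def test_tie_break_is_lexicographic(self):
        res = pd.DataFrame({"p_t": [1e-6, 1e-6, 1e-3]}, index=["zzz", "aaa", "mmm"])
        sig = select_signature(res, 1e-2)
        assert sig.feature_ids == ("aaa", "zzz", "mmm")


class TestCompareTests:
    def test_identical_and_disjoint_cases(self):
        res = pd.DataFrame(
            {"p_t": [1e-5, 0.5], "p_wilcoxon": [1e-5, 0.5]}, index=["a", "b"]
        )
        out = compare_tests(res, 1e-3)
        assert out["n_overlap"] == 1 and out["overlap_of_smaller"] == 1.0
        res2 = pd.DataFrame(
            {"p_t": [1e-5, 0.5], "p_wilcoxon": [0.5, 1e-5]}, index=["a", "b"]
        )
        assert compare_tests(res2, 1e-3)["n_overlap"] == 0

    def test_planted_effects_give_high_overlap(self):
        ds = generate_paired_dataset(SimulationConfig(seed=1))
        res = de_table(ds.ct, ds.annotation)
        out = compare_tests(res, 1e-3)
        assert out["overlap_of_smaller"] >= 0.8
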