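"""Normalization, BH FDR, NB-Wald DE and the selection filters, each checked
against direct re-computation oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isoshift.de import (
    FilterThresholds,
    bh_fdr,
    nb_wald_de,
    select_abundant,
    select_top_expressed,
    size_factors,
    to_fpkm,
    to_rpm,
)
from isoshift.simulate import SimulationConfig, simulate_gene_counts


class TestSizeFactors:
    def test_doubled_sample_forced_factors(self):
        counts = pd.DataFrame({"s1": [10, 40, 7], "s2": [20, 80, 14]})
        sf = size_factors(counts)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2], "c": [5, 9, 2]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_matches_bruteforce_median_of_ratios(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, size=(50, 5)).astype(float))
        sf = size_factors(counts)
        # feature-by-feature re-computation of the estimator's definition
        c = counts.to_numpy()
        rows = c[(c > 0).all(axis=1)]
        geo = np.exp(np.mean(np.log(rows), axis=1))
        expected = [np.median(rows[:, j] / geo) for j in range(c.shape[1])]
        assert np.allclose(sf.to_numpy(), expected)

    def test_no_all_nonzero_feature_raises(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [5, 0]})
        with pytest.raises(ValueError, match="size factors undefined"):
            size_factors(counts)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 500, size=(40, 4)).astype(float))
        sf = size_factors(counts)
        scaled = counts.copy()
        scaled.iloc[:, 0] *= 3.0
        sf2 = size_factors(scaled)
        assert sf2.iloc[0] / sf.iloc[0] == pytest.approx(3.0 ** (3 / 4), rel=1e-9)


class TestRpmFpkm:
    def test_rpm_simple_and_column_sums(self):
        counts = pd.DataFrame({"s": [50, 50]})
        assert (to_rpm(counts)["s"] == [500_000, 500_000]).all()
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.integers(1, 100, size=(30, 6)))
        assert np.allclose(to_rpm(mat).sum(axis=0), 1e6, rtol=1e-6)

    def test_single_feature_rpm_is_one_million(self):
        assert to_rpm(pd.DataFrame({"s": [7]}))["s"].iloc[0] == 1e6

    def test_fpkm_unit_case(self):
        counts = pd.DataFrame({"s": [1e6]}, index=["g"])
        lengths = pd.Series({"g": 1000})
        assert to_fpkm(counts, lengths)["s"].iloc[0] == pytest.approx(1e6)

    def test_fpkm_length_scaling(self):
        counts = pd.DataFrame({"s": [100.0, 200.0]}, index=["g1", "g2"])
        f1 = to_fpkm(counts, pd.Series({"g1": 1000, "g2": 2000}))
        f2 = to_fpkm(counts, pd.Series({"g1": 2000, "g2": 2000}))
        # doubling g1's length halves its FPKM under the fixed-depth convention
        assert f2.loc["g1", "s"] == pytest.approx(f1.loc["g1", "s"] / 2)
        assert f2.loc["g2", "s"] == pytest.approx(f1.loc["g2", "s"])

    def test_fpkm_matches_formula(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.uniform(1, 1000, size=(20, 4)))
        lengths = pd.Series(rng.integers(500, 5000, size=20), index=counts.index)
        f = to_fpkm(counts, lengths)
        depth = counts.sum(axis=0) / 1e6
        for i in counts.index:
            for j in counts.columns:
                expected = counts.loc[i, j] / (lengths[i] / 1e3) / depth[j]
                assert f.loc[i, j] == pytest.approx(expected)

    def test_missing_length_raises(self):
        counts = pd.DataFrame({"s": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="missing gene lengths"):
            to_fpkm(counts, pd.Series(dtype=float))


class TestBhFdr:
    def test_uniform_ladder_forced_values(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
    def test_matches_min_over_suffix_definition(self, p):
        q = bh_fdr(p)
        n = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(n)
        for rank, i in enumerate(order, start=1):
            expected[i] = min(
                min(p[j] * n / (r + 1) for r, j in enumerate(order) if r + 1 >= rank),
                1.0,
            )
        assert np.allclose(q, expected)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        assert np.allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1])


class TestNbWaldDe:
    def test_label_symmetry(self):
        cfg = SimulationConfig(n_genes=200, rng_seed=5)
        counts, _ = simulate_gene_counts(cfg, gene_effects={"GENE00001": 1.5})
        de_fwd = nb_wald_de(counts, cfg.groups, reference_group="shLuc")
        de_rev = nb_wald_de(counts, cfg.groups, reference_group="shCD44")
        assert np.allclose(de_fwd["log2FC"], -de_rev["log2FC"])
        assert np.allclose(de_fwd["pvalue"], de_rev["pvalue"])

    def test_identical_permuted_groups_give_zero_fold_changes(self):
        # group 2 is a permutation of group 1's samples: symmetry forces lfc ~ 0
        cfg = SimulationConfig(n_genes=500, rng_seed=6)
        counts, _ = simulate_gene_counts(cfg, gene_effects={})
        g1_cols = list(cfg.groups[cfg.groups == "shLuc"].index)
        perm = g1_cols[::-1]
        dup = pd.concat(
            [counts[g1_cols], counts[perm].set_axis([f"p{i}" for i in range(len(perm))], axis=1)],
            axis=1,
        )
        groups = pd.Series(
            ["g1"] * len(g1_cols) + ["g2"] * len(perm), index=dup.columns
        )
        de = nb_wald_de(dup, groups)
        assert de["log2FC"].abs().median() < 0.1

    def test_parameter_recovery_mae(self):
        # planted log2FC recovered with MAE < 0.25 at mean count >= 200, n=7/8
        cfg = SimulationConfig(
            n_genes=400, rng_seed=7, gene_log_mean=np.log(400), gene_log_sigma=0.5
        )
        rng = np.random.default_rng(0)
        eff = {f"GENE{i+1:05d}": float(s) for i, s in enumerate(
            rng.choice([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0], size=80))}
        counts, _ = simulate_gene_counts(cfg, gene_effects=eff)
        de = nb_wald_de(counts, cfg.groups)
        keep = [g for g in eff if de.loc[g, "baseMean"] >= 200]
        err = np.abs([de.loc[g, "log2FC"] - eff[g] for g in keep])
        assert len(keep) > 40
        assert err.mean() < 0.25

    def test_qvalue_dominates_pvalue(self):
        cfg = SimulationConfig(n_genes=300, rng_seed=8)
        counts, _ = simulate_gene_counts(cfg, gene_effects={})
        de = nb_wald_de(counts, cfg.groups)
        assert (de["qvalue"] >= de["pvalue"] - 1e-12).all()
        assert de["qvalue"].between(0, 1).all()

    def test_single_sample_group_rejected(self):
        counts = pd.DataFrame(np.ones((5, 3)), columns=["a", "b", "c"])
        groups = pd.Series(["g1", "g1", "g2"], index=["a", "b", "c"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            nb_wald_de(counts, groups)


class TestSelection:
    def test_cumulative_share_forced_example(self):
        means = [0.5e6, 0.3e6, 0.15e6, 0.03e6, 0.015e6, 0.005e6]
        rpm = pd.DataFrame({"s1": means, "s2": means},
                           index=[f"iso{i}" for i in range(6)])
        chosen = select_abundant(rpm, FilterThresholds(cum_fraction=0.95))
        assert chosen == ["iso0", "iso1", "iso2"]

    def test_cum_fraction_one_keeps_all_above_threshold(self):
        rpm = pd.DataFrame({"s": [1e6 - 350, 200, 150, 50]},
                           index=["a", "b", "c", "d"])
        chosen = select_abundant(rpm, FilterThresholds(cum_fraction=1.0))
        assert chosen == ["a", "b", "c"]  # d fails the 100-RPM floor

    def test_matches_bruteforce_prefix_search(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            vals = rng.uniform(0, 1, size=12)
            rpm = pd.DataFrame({"s": vals / vals.sum() * 1e6},
                               index=[f"i{k:02d}" for k in range(12)])
            thr = FilterThresholds(min_mean_rpm=100.0, cum_fraction=0.9)
            chosen = select_abundant(rpm, thr)
            means = rpm.mean(axis=1)
            kept = means[means > 100.0].sort_values(ascending=False)
            total = means.sum()
            expected, cum = [], 0.0
            for label, v in kept.items():
                expected.append(label)
                cum += v
                if cum / total >= 0.9:
                    break
            assert chosen == expected

    def test_ties_broken_by_label(self):
        rpm = pd.DataFrame({"s": [400.0, 400.0, 200.0]}, index=["b", "a", "c"])
        chosen = select_abundant(rpm, FilterThresholds(cum_fraction=0.4))
        assert chosen == ["a"]

    def test_top_expressed_trivial_cases(self):
        fpkm = pd.DataFrame({"s": [5.0, 9.0, 2.0]}, index=["g1", "g2", "g3"])
        assert select_top_expressed(fpkm, 1) == ["g2"]
        assert set(select_top_expressed(fpkm, 3)) == {"g1", "g2", "g3"}
        with pytest.raises(ValueError):
            select_top_expressed(fpkm, 4)

    def test_top_expressed_matches_sort_oracle(self):
        rng = np.random.default_rng(10)
        fpkm = pd.DataFrame(rng.uniform(size=(30, 4)),
                            index=[f"g{k:02d}" for k in range(30)])
        got = select_top_expressed(fpkm, 10)
        expected = list(fpkm.mean(axis=1).sort_values(ascending=False, kind="stable").index[:10])
        assert got == expected
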