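"""Generator invariants: determinism, planted-truth consistency, NB moments."""

import numpy as np
import pandas as pd
import pytest

from isoshift.reference import IsomirId
from isoshift.simulate import (
    ADAPTER,
    READ_LENGTH,
    SimulationConfig,
    generate,
    make_reference,
    make_read,
    nb_draws,
    simulate_gene_counts,
    simulate_smallrna_reads,
)


class TestConfig:
    def test_rejects_sub_twofold_effects(self):
        cfg = SimulationConfig(planted_isomir_effects={"x|0": 0.5})
        with pytest.raises(ValueError, match="log2 effects"):
            cfg.validate()

    def test_rejects_nonpositive_dispersion(self):
        with pytest.raises(ValueError):
            SimulationConfig(nb_dispersion=0.0).validate()


class TestReference:
    def test_mature_embedded_at_recorded_coordinates(self):
        ref = make_reference(SimulationConfig(n_mirnas=1, rng_seed=7))
        (m,) = ref.matures
        hp = ref.hairpins[m.hairpin]
        assert hp[m.start : m.end] == ref.mature_seq(m.name)
        assert 20 <= m.end - m.start <= 24
        assert len(hp) >= (m.end - m.start) + 10

    def test_prefixes_pairwise_distinct(self):
        # exhaustive pairwise comparison over a 50-miRNA reference
        ref = make_reference(SimulationConfig(n_mirnas=50, rng_seed=2))
        seqs = [ref.mature_seq(m.name) for m in ref.matures]
        assert len(seqs) == 50
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                assert seqs[i][:16] != seqs[j][:16]

    def test_same_seed_is_deterministic(self, tmp_path):
        cfg = SimulationConfig(n_mirnas=5, rng_seed=11)
        a, b = make_reference(cfg), make_reference(cfg)
        assert a.hairpins == b.hairpins and a.matures == b.matures
        a.write(tmp_path / "h1.fa", tmp_path / "m1.tsv")
        b.write(tmp_path / "h2.fa", tmp_path / "m2.tsv")
        assert (tmp_path / "h1.fa").read_bytes() == (tmp_path / "h2.fa").read_bytes()
        assert (tmp_path / "m1.tsv").read_bytes() == (tmp_path / "m2.tsv").read_bytes()


class TestReads:
    def test_read_structure_isoform_adapter_padding(self):
        rng = np.random.default_rng(0)
        iso = "ACGTACGTACGTACGTACGTAC"  # 22 nt
        read = make_read(iso, rng)
        assert len(read) == READ_LENGTH
        assert read.startswith(iso + ADAPTER)

    def test_degenerate_profile_all_reads_from_one_isoform(self):
        cfg = SimulationConfig(
            n_mirnas=1, n_isoforms_per_mirna=1, n_samples_per_group=(1, 1),
            depth_smallrna=100, rng_seed=5,
        )
        ref = make_reference(cfg)
        label = IsomirId(ref.matures[0].name, 0).label
        sim = simulate_smallrna_reads(
            ref, cfg, effects={}, baseline=pd.Series({label: 1.0})
        )
        mature = ref.mature_seq(ref.matures[0].name)
        for recs in sim.reads.values():
            assert len(recs) == 100
            assert all(seq.startswith(mature) for _, seq in recs)

    def test_depth_conserved_exactly(self, small_bundle):
        depth = small_bundle.config.depth_smallrna
        assert (small_bundle.read_sim.tallies.sum(axis=0) == depth).all()
        assert all(len(r) == depth for r in small_bundle.read_sim.reads.values())

    def test_empirical_proportions_within_three_binomial_se(self):
        cfg = SimulationConfig(
            n_mirnas=1, n_isoforms_per_mirna=3, n_samples_per_group=(1, 1),
            depth_smallrna=100_000, rng_seed=9,
        )
        ref = make_reference(cfg)
        name = ref.matures[0].name
        baseline = pd.Series(
            {f"{name}|0": 0.5, f"{name}|+1": 0.3, f"{name}|-1": 0.2}
        )
        sim = simulate_smallrna_reads(ref, cfg, effects={}, baseline=baseline)
        n = cfg.depth_smallrna
        for sample in sim.tallies.columns:
            for label, p in baseline.items():
                se = np.sqrt(p * (1 - p) / n)
                assert abs(sim.tallies.loc[label, sample] / n - p) < 3 * se

    def test_unplantable_isomir_rejected(self):
        cfg = SimulationConfig(n_mirnas=1, rng_seed=5)
        ref = make_reference(cfg)
        with pytest.raises(ValueError, match="not generatable"):
            simulate_smallrna_reads(ref, cfg, effects={"no-such-mir|0": 1.5})


class TestGeneCounts:
    def test_poisson_limit_variance_matches_mean(self):
        rng = np.random.default_rng(0)
        draws = nb_draws(rng, np.full(10_000, 100.0), dispersion=1e-13)
        assert abs(draws.mean() - 100) < 1.0
        assert abs(draws.var() / draws.mean() - 1.0) < 0.1

    def test_nb_moments(self):
        rng = np.random.default_rng(1)
        mu, a = 200.0, 0.2
        draws = nb_draws(rng, np.full(20_000, mu), dispersion=a)
        expected_var = mu + a * mu * mu
        assert abs(draws.var() / expected_var - 1.0) < 0.1

    def test_planted_fold_change_realized(self):
        cfg = SimulationConfig(n_genes=50, rng_seed=4, nb_dispersion=0.05)
        counts, _ = simulate_gene_counts(cfg, gene_effects={"GENE00001": -1.0})
        g = cfg.groups
        m1 = counts.loc["GENE00001", g[g == "shLuc"].index].mean()
        m2 = counts.loc["GENE00001", g[g == "shCD44"].index].mean()
        assert 0.3 < m2 / m1 < 0.75

    def test_null_t_statistics_approximately_standard_normal(self):
        cfg = SimulationConfig(n_genes=2000, rng_seed=8)
        counts, _ = simulate_gene_counts(cfg, gene_effects={})
        logc = np.log2(counts.to_numpy() + 1.0)
        g = cfg.groups.to_numpy()
        a, b = logc[:, g == "shLuc"], logc[:, g == "shCD44"]
        n1, n2 = a.shape[1], b.shape[1]
        sp = ((n1 - 1) * a.var(1, ddof=1) + (n2 - 1) * b.var(1, ddof=1)) / (n1 + n2 - 2)
        t = (b.mean(1) - a.mean(1)) / np.sqrt(sp * (1 / n1 + 1 / n2))
        assert abs(t.mean()) < 0.1
        assert 0.85 < t.std() < 1.25


class TestUtrsAndTables:
    def test_planted_sites_are_seed_reverse_complements(self, small_bundle):
        # every planted target UTR contains the DNA revcomp of its isomiR's 6mer seed
        from isoshift.targets import seed_of, site_patterns
        b = small_bundle
        for label, genes in b.truth.true_targets.items():
            iso_seq = b.reference.isoform_seq(
                _iso(label)
            )
            (site,) = site_patterns(seed_of(iso_seq))
            for g in genes:
                assert site in b.tables.utrs[g], (label, g)

    def test_non_target_utrs_contain_no_active_site(self, small_bundle):
        from isoshift.targets import seed_of, site_patterns
        b = small_bundle
        sites = {
            label: site_patterns(seed_of(b.reference.isoform_seq(_iso(label))))[0]
            for label in b.truth.true_isomir_fc
        }
        targeted = {g for gs in b.truth.true_targets.values() for g in gs}
        for gene, utr in b.tables.utrs.items():
            if gene in targeted:
                continue
            for label, site in sites.items():
                assert site not in utr, (gene, label)

    def test_zero_decoy_tf_table_equals_truth_edges(self):
        cfg = SimulationConfig(
            n_mirnas=6, n_genes=200, depth_smallrna=1000, n_decoy_tfs=0,
            decoy_rate=0.0, rng_seed=6,
        )
        b = generate(cfg)
        truth_edges = {
            (tf, g)
            for tf, d in b.truth.true_tf_regulators.items()
            for g in d["genes"]
        }
        table_edges = set(map(tuple, b.tables.tf_gene[["tf", "gene"]].to_numpy()))
        assert table_edges == truth_edges

    def test_full_bundle_determinism(self, tmp_path):
        cfg = SimulationConfig(n_mirnas=4, n_genes=100, depth_smallrna=500, rng_seed=13)
        p1 = generate(cfg).write(tmp_path / "a")
        p2 = generate(cfg).write(tmp_path / "b")
        for key in p1:
            if key == "reads_dir":
                for fq in sorted(p1[key].glob("*.fastq")):
                    assert fq.read_bytes() == (p2[key] / fq.name).read_bytes()
            else:
                assert p1[key].read_bytes() == p2[key].read_bytes(), key


def _iso(label):
    name, _, shift = label.rpartition("|")
    return IsomirId(name, int(shift))
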