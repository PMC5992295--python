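"""Ground-truth guarantees of the paired-virome simulator."""

from __future__ import annotations

import numpy as np
import pytest

from viropair.homology import revcomp
from viropair.synth import (
    SimulationConfig,
    community_contigs,
    generate_genomes,
    generate_hit_table,
    generate_pair_communities,
    simulate_pair_study,
    simulate_reads,
)


def small_config(**kw) -> SimulationConfig:
    base = dict(
        n_genomes_pool=60,
        genome_length_range=(400, 800),
        n_pairs=3,
        genomes_per_sample=10,
        shared_fraction=0.3,
        background_shared_fraction=0.0,
        n_reads_per_sample=200,
        read_length=100,
        substitution_error_rate=0.0,
        rng_seed=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateGenomes:
    def test_empty_catalogue(self):
        assert generate_genomes(0) == {}

    def test_gc_within_binomial_bound(self):
        # 4 binomial SD at n=10,000, p=0.5 is ~0.02
        cat = generate_genomes(50, (10000, 10000), 0.5, rng=3)
        for g in cat.values():
            gc = (g.seq.count("G") + g.seq.count("C")) / len(g.seq)
            assert abs(gc - 0.5) < 0.02

    def test_lengths_in_range_and_alphabet(self):
        cat = generate_genomes(20, (500, 900), 0.45, rng=4)
        for g in cat.values():
            assert 500 <= len(g.seq) <= 900
            assert set(g.seq) <= set("ACGT")

    def test_same_seed_identical(self):
        a = generate_genomes(10, (500, 600), 0.4, rng=11)
        b = generate_genomes(10, (500, 600), 0.4, rng=11)
        assert {k: v.seq for k, v in a.items()} == {k: v.seq for k, v in b.items()}
        assert {k: v.family for k, v in a.items()} == {k: v.family for k, v in b.items()}

    def test_bad_length_range_rejected(self):
        with pytest.raises(ValueError):
            generate_genomes(5, (0, 100))


class TestPairCommunities:
    @pytest.mark.parametrize(
        "shared,expected",
        [(0.0, 0), (0.3, 3), (1.0, 10)],
    )
    def test_planted_shared_count_exact(self, shared, expected):
        cfg = small_config(shared_fraction=shared)
        cat = generate_genomes(cfg.n_genomes_pool, cfg.genome_length_range, 0.45, rng=2)
        comms = generate_pair_communities(cat, cfg)
        for p in range(cfg.n_pairs):
            milk = set(comms[f"pair{p}_milk"])
            stool = set(comms[f"pair{p}_stool"])
            assert len(milk & stool) == expected
            assert len(milk) == len(stool) == cfg.genomes_per_sample

    def test_abundances_normalized(self):
        cfg = small_config()
        cat = generate_genomes(cfg.n_genomes_pool, cfg.genome_length_range, 0.45, rng=2)
        comms = generate_pair_communities(cat, cfg)
        for table in comms.values():
            assert np.isclose(sum(table.values()), 1.0)

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            small_config(n_genomes_pool=5, genomes_per_sample=10)


class TestSimulateReads:
    def _setup(self, **kw):
        cfg = small_config(**kw)
        cat = generate_genomes(2, (600, 600), 0.45, rng=5)
        ids = sorted(cat)
        community = {ids[0]: 0.9, ids[1]: 0.1}
        return cfg, cat, community

    def test_error_free_reads_are_exact_substrings(self):
        cfg, cat, community = self._setup()
        reads, _ = simulate_reads(community, cat, cfg, np.random.default_rng(6))
        for r in reads:
            genome = cat[r.source_genome].seq
            frag = genome[r.position : r.position + cfg.read_length]
            assert r.seq == (frag if r.strand == "+" else revcomp(frag))

    def test_read_length_and_count_exact(self):
        cfg, cat, community = self._setup(n_reads_per_sample=137)
        reads, rmap = simulate_reads(community, cat, cfg, np.random.default_rng(6))
        assert len(reads) == 137
        assert all(len(r.seq) == cfg.read_length for r in reads)
        assert set(rmap) == {r.id for r in reads}

    def test_multinomial_split_within_3_sd(self):
        cfg, cat, community = self._setup(n_reads_per_sample=10000)
        reads, _ = simulate_reads(community, cat, cfg, np.random.default_rng(8))
        major = sorted(community, key=community.get)[-1]
        n_major = sum(r.source_genome == major for r in reads)
        sd = np.sqrt(10000 * 0.9 * 0.1)  # ~30
        assert abs(n_major - 9000) <= 3 * sd

    def test_error_rate_marks_low_quality(self):
        cfg, cat, community = self._setup(substitution_error_rate=0.05)
        reads, _ = simulate_reads(community, cat, cfg, np.random.default_rng(9))
        n_err = n_err_lowq = 0
        for r in reads:
            genome = cat[r.source_genome].seq
            frag = genome[r.position : r.position + cfg.read_length]
            if r.strand == "-":
                frag = revcomp(frag)
            for s, t, q in zip(r.seq, frag, r.qual):
                if s != t:
                    n_err += 1
                    n_err_lowq += ord(q) - 33 < 30
        assert n_err > 0
        assert n_err_lowq == n_err  # every planted error carries low quality

    def test_empty_community_rejected(self):
        cfg, cat, _ = self._setup()
        with pytest.raises(ValueError):
            simulate_reads({}, cat, cfg)


class TestFullStudy:
    def test_byte_identical_under_same_config(self):
        cfg = small_config()
        r1, t1 = simulate_pair_study(cfg)
        r2, t2 = simulate_pair_study(cfg)
        assert {s: [(x.id, x.seq, x.qual) for x in rs] for s, rs in r1.items()} == {
            s: [(x.id, x.seq, x.qual) for x in rs] for s, rs in r2.items()
        }
        assert t1.communities == t2.communities

    def test_read_conservation_and_truth_links(self):
        cfg = small_config()
        reads, truth = simulate_pair_study(cfg)
        for sample, rs in reads.items():
            assert len(rs) == cfg.n_reads_per_sample
            for r in rs:
                assert r.source_genome in truth.catalogue
                assert r.source_genome in truth.communities[sample]

    def test_community_contigs_reflect_genome_sharing(self):
        cfg = small_config(genome_length_range=(2200, 2600))
        cat = generate_genomes(cfg.n_genomes_pool, cfg.genome_length_range, 0.45, rng=2)
        comms = generate_pair_communities(cat, cfg)
        viromes = community_contigs(comms, cat)
        milk, stool = viromes["pair0_milk"], viromes["pair0_stool"]
        shared = {g for g in comms["pair0_milk"]} & {g for g in comms["pair0_stool"]}
        milk_genomes = {cid.split("|")[1] for cid in milk}
        stool_genomes = {cid.split("|")[1] for cid in stool}
        assert milk_genomes & stool_genomes == shared


class TestHitTable:
    def test_truth_family_is_best_hit_below_threshold(self):
        rows, fam_map = generate_hit_table(
            {"c1": "Siphoviridae", "c2": None}, rng=3
        )
        c1_rows = [r for r in rows if r[0] == "c1"]
        best = min(c1_rows, key=lambda r: r[10])
        assert fam_map[best[1]] == "Siphoviridae"
        assert best[10] < 1e-20
        c2_rows = [r for r in rows if r[0] == "c2"]
        assert c2_rows and all(r[10] > 1e-20 for r in c2_rows)

    def test_empty_input(self):
        rows, fam_map = generate_hit_table({})
        assert rows == [] and fam_map == {}

    def test_rows_have_12_columns(self):
        rows, _ = generate_hit_table({"c": "Myoviridae"}, rng=1)
        assert all(len(r) == 12 for r in rows)
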