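"""Synthetic community generator: planted structure, sequences, genomes."""

import numpy as np
import pytest
from scipy.stats import binom

from phagenet import (
    Proteome,
    SimConfig,
    generate_community,
    generate_genome,
    generate_sequences,
)
from phagenet.compgen import detect_dtr, gc_content


def shared(p1, p2):
    return len(p1.families & p2.families)


class TestGenerateCommunity:
    def test_planted_partition_structure(self, planted_community):
        proteomes, truth = planted_community
        assert len(proteomes) == 30
        assert set(truth.partition) == {p.genome_id for p in proteomes}
        by_id = {p.genome_id: p for p in proteomes}
        for g1 in by_id.values():
            for g2 in by_id.values():
                if g1.genome_id >= g2.genome_id:
                    continue
                if truth.partition[g1.genome_id] == truth.partition[g2.genome_id]:
                    assert shared(g1, g2) >= 20  # all core families shared
                else:
                    non_bg = {
                        f
                        for f in g1.families & g2.families
                        if truth.family_origin[f] != "background"
                    }
                    assert not non_bg

    def test_minimal_community_identical_repertoires(self):
        config = SimConfig(n_clusters=1, genomes_per_cluster=2, core_families_per_cluster=5)
        proteomes, truth = generate_community(config)
        assert len(proteomes) == 2
        assert proteomes[0].families == proteomes[1].families
        assert len(proteomes[0].families) == 5
        assert all(v == "C1" for v in truth.family_origin.values())

    def test_empty_community(self):
        proteomes, truth = generate_community(
            SimConfig(n_clusters=0, genomes_per_cluster=5, core_families_per_cluster=5)
        )
        assert proteomes == []
        assert truth.partition == {}

    def test_mosaic_draws_follow_binomial_mixture(self):
        """50/50 mosaic core counts stay within binomial(20, 0.5) bounds."""
        lo = binom.ppf(1e-4, 20, 0.5)
        hi = binom.ppf(1 - 1e-4, 20, 0.5)
        counts = []
        for seed in range(100):
            config = SimConfig(
                n_clusters=3,
                genomes_per_cluster=10,
                core_families_per_cluster=20,
                accessory_families_per_cluster=10,
                background_families_per_genome=3,
                n_mosaic=1,
                mosaic_mixture=(0.5, 0.5, 0.0),
                seed=seed,
            )
            proteomes, truth = generate_community(config)
            mosaic = next(p for p in proteomes if p.genome_id in truth.mosaic_ids)
            for cid in ("C1", "C2"):
                n = sum(1 for f in mosaic.families if f.startswith(f"{cid}.core"))
                counts.append(n)
            assert not any(f.startswith("C3.") for f in mosaic.families)
        counts = np.array(counts)
        assert (counts >= lo).all() and (counts <= hi).all()
        assert abs(counts.mean() - 10.0) < 1.0

    def test_determinism(self):
        config = SimConfig(3, 10, 20, 10, 0.5, 3, 1, (0.2, 0.3, 0.5), seed=42)
        out1 = generate_community(config)
        out2 = generate_community(config)
        assert [p.families for p in out1[0]] == [p.families for p in out2[0]]
        assert out1[1].partition == out2[1].partition

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_clusters": -1, "genomes_per_cluster": 2, "core_families_per_cluster": 5},
            {"n_clusters": 2, "genomes_per_cluster": 2, "core_families_per_cluster": 5,
             "accessory_carry_prob": 1.5},
            {"n_clusters": 2, "genomes_per_cluster": 2, "core_families_per_cluster": 5,
             "n_mosaic": 1, "mosaic_mixture": (0.5,)},
            {"n_clusters": 2, "genomes_per_cluster": 2, "core_families_per_cluster": 5,
             "n_mosaic": 1, "mosaic_mixture": (0.7, 0.7)},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestGenerateSequences:
    def test_identity_one_gives_byte_identical_members(self):
        proteomes = [Proteome(f"g{i}", {"fam1", "fam2"}) for i in range(3)]
        seqs = generate_sequences(proteomes, target_identity=1.0, seed=0)
        by_family = {}
        for pid, fam in seqs.family_of.items():
            by_family.setdefault(fam, set()).add(seqs.sequences[pid])
        assert all(len(variants) == 1 for variants in by_family.values())

    def test_within_family_identity_matches_analytic_expectation(self):
        """Two copies mutated at rate 0.2: E[identity] = t^2 + (1-t)^2/19."""
        expected = 0.8 ** 2 + 0.2 ** 2 / 19
        proteomes = [Proteome("gA", {f"fam{i}" for i in range(200)}),
                     Proteome("gB", {f"fam{i}" for i in range(200)})]
        seqs = generate_sequences(proteomes, target_identity=0.8, seed=3)
        idents = []
        for i in range(200):
            a = seqs.sequences[f"gA.p{i + 1:03d}"]
            b = seqs.sequences[f"gB.p{i + 1:03d}"]
            assert seqs.family_of[f"gA.p{i + 1:03d}"] == seqs.family_of[f"gB.p{i + 1:03d}"]
            idents.append(np.mean([x == y for x, y in zip(a, b)]))
        assert abs(np.mean(idents) - expected) < 0.01
        assert 0.5 <= min(idents) and max(idents) <= 1.0

    def test_between_family_identity_near_random_match_rate(self):
        proteomes = [Proteome("g", {f"fam{i}" for i in range(100)})]
        seqs = generate_sequences(proteomes, target_identity=1.0, seed=5)
        ordered = sorted(seqs.sequences)
        idents = [
            np.mean(
                [x == y for x, y in zip(seqs.sequences[a], seqs.sequences[b])]
            )
            for a, b in zip(ordered[::2], ordered[1::2])
        ]
        assert abs(np.mean(idents) - 0.05) < 0.01

    def test_family_sizes_preserved(self, planted_community):
        proteomes, _ = planted_community
        seqs = generate_sequences(proteomes, seed=0)
        emitted = {}
        for fam in seqs.family_of.values():
            emitted[fam] = emitted.get(fam, 0) + 1
        expected = {}
        for p in proteomes:
            for fam in p.families:
                expected[fam] = expected.get(fam, 0) + 1
        assert emitted == expected

    def test_identity_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="target_identity"):
            generate_sequences([Proteome("g", {"f"})], target_identity=0.2)


class TestGenerateGenome:
    def test_planted_dtr_detected(self):
        genome = generate_genome(45403, dtr_length=208, gc=0.4589, seed=7)
        assert len(genome) == 45403
        assert detect_dtr(genome) == 208

    def test_gc_control(self):
        genome = generate_genome(20000, dtr_length=0, gc=0.4589, seed=2)
        assert abs(gc_content(genome) - 45.89) < 2.0

    def test_no_planted_repeat_detects_nothing(self):
        genome = generate_genome(1000, dtr_length=0, gc=0.5, seed=11)
        assert detect_dtr(genome) < 20

    def test_tiny_genome_prefix_equals_suffix(self):
        genome = generate_genome(10, dtr_length=5, gc=0.5, seed=0)
        assert genome[:5] == genome[-5:]

    def test_excessive_dtr_rejected(self):
        with pytest.raises(ValueError, match="dtr_length"):
            generate_genome(100, dtr_length=51, gc=0.5)
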