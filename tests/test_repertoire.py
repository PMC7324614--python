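import math

import numpy as np
import pytest

from oracles import brute_hamming_edges

import sumiseq as sq
from sumiseq.dna import random_dna, translate
from sumiseq.repertoire import (
    AnnotatedBCR,
    clone_reads,
    filter_bcr,
    renyi_index,
    shm_stats,
    viz_subsample,
)


def bcr(seq, cdr3="AAATTT", v="V1", j="J1", abundance=1, mutations=(), v_mm=0,
        in_frame=True):
    return AnnotatedBCR(
        sequence=seq, v_gene=v, j_gene=j, v_mismatches=v_mm,
        mutations=list(mutations), cdr3_nt=cdr3,
        cdr3_aa=translate(cdr3) if in_frame else "", in_frame=in_frame,
        abundance=abundance,
    )


class TestFilterBCR:
    def test_unmutated_templates_round_trip(self, germline):
        cfg = sq.SimulationConfig(n_templates=20, shm_rate=0.0, seed=31)
        templates = sq.generate_templates(cfg, germline)
        annotated, rejected = filter_bcr(
            [t.full_sequence for t in templates], germline
        )
        assert not rejected
        truth = {t.full_sequence: t for t in templates}
        for a in annotated:
            t = truth[a.sequence]
            assert (a.v_gene, a.j_gene) == (t.v_gene, t.j_gene)
            assert a.v_mismatches == 0 and a.mutations == []
            assert a.cdr3_nt == t.cdr3_nt
            assert a.in_frame

    def test_random_dna_rejected(self, germline, rng):
        seqs = [random_dna(rng, 220) for _ in range(20)]
        annotated, rejected = filter_bcr(seqs, germline)
        assert not annotated and len(rejected) == 20

    def test_internal_stop_codon_rejected(self, germline):
        cfg = sq.SimulationConfig(n_templates=1, shm_rate=0.0, seed=32)
        t = sq.generate_templates(cfg, germline)[0]
        # plant TAA in-frame inside the V segment, past the primer site
        seq = t.full_sequence
        broken = seq[:60] + "TAA" + seq[63:]
        annotated, rejected = filter_bcr([broken], germline)
        assert not annotated
        assert rejected[0][1] == "no_orf"

    def test_silent_vs_nonsilent_classification(self, germline):
        cfg = sq.SimulationConfig(n_templates=1, shm_rate=0.0, seed=33)
        t = sq.generate_templates(cfg, germline)[0]
        v = germline[t.v_gene].sequence
        silent_pos = None
        for c0 in range(30, len(v) - 3, 3):  # skip the primer site
            codon = v[c0 : c0 + 3]
            for b in "ACGT":
                if b != codon[2] and translate(codon[:2] + b) == translate(codon):
                    silent_pos, new_base = c0 + 2, b
                    break
            if silent_pos:
                break
        assert silent_pos is not None
        mutated = (
            t.full_sequence[:silent_pos] + new_base + t.full_sequence[silent_pos + 1 :]
        )
        annotated, _ = filter_bcr([mutated], germline)
        assert len(annotated) == 1
        muts = annotated[0].mutations
        assert len(muts) == 1 and muts[0].effect == "silent"
        stats = shm_stats(annotated)
        assert stats["silent_to_nonsilent_ratio"] is None  # 0 denominator

    def test_duplicates_accumulate_abundance(self, germline):
        cfg = sq.SimulationConfig(n_templates=1, shm_rate=0.0, seed=34)
        t = sq.generate_templates(cfg, germline)[0]
        annotated, _ = filter_bcr([t.full_sequence] * 5, germline)
        assert len(annotated) == 1 and annotated[0].abundance == 5


class TestBuildNetwork:
    def test_basic_vertices_edges_clusters(self):
        g = sq.build_network([bcr("ACGT", abundance=3), bcr("ACGA")])
        assert g.graph.nodes["ACGT"]["abundance"] == 3
        assert g.graph.nodes["ACGA"]["abundance"] == 1
        assert g.edges == [("ACGT", "ACGA")] or g.edges == [("ACGA", "ACGT")]
        assert len(g.clusters()) == 1

    def test_indel_difference_never_joins(self):
        g = sq.build_network([bcr("ACGT"), bcr("ACGTA")])
        assert g.edges == []
        assert len(g.clusters()) == 2

    def test_matches_bruteforce_oracle(self, rng):
        seqs = []
        for _ in range(20):
            anc = random_dna(rng, 30)
            seqs.append(anc)
            for _ in range(int(rng.integers(1, 8))):
                pos = int(rng.integers(30))
                alt = "ACGT"[int(rng.integers(4))]
                seqs.append(anc[:pos] + alt + anc[pos + 1 :])
        g = sq.build_network([bcr(s) for s in seqs])
        got = {tuple(sorted(e)) for e in g.edges}
        want = {tuple(sorted(e)) for e in brute_hamming_edges(seqs)}
        assert got == want


class TestDefineClones:
    def test_single_component_single_clone(self):
        g = sq.build_network([bcr("ACGT"), bcr("ACGA")])
        clones = sq.define_clones(g, [bcr("ACGT"), bcr("ACGA")])
        assert len(clones) == 1
        assert clones[0].unique_sequences == 2

    def test_identical_cdr3_and_genes_merge_components(self):
        a, b = bcr("AAAAAA", cdr3="TTTTTT"), bcr("CCCCCC", cdr3="TTTTTT")
        g = sq.build_network([a, b])
        assert len(g.clusters()) == 2  # Hamming distance 6: disconnected
        clones = sq.define_clones(g, [a, b])
        assert len(clones) == 1

    def test_distinct_cdr3_stay_separate(self):
        a, b = bcr("AAAAAA", cdr3="TTTTTT"), bcr("CCCCCC", cdr3="GGGGGG")
        clones = sq.define_clones(sq.build_network([a, b]), [a, b])
        assert len(clones) == 2

    def test_simulated_clone_recovery(self, germline):
        k = 5
        cfg = sq.SimulationConfig(
            n_templates=40, template_pool_fractions=[1 / k] * k,
            synthetic_umi_length=0, shm_rate=0.0, seed=35,
        )
        templates = sq.generate_templates(cfg, germline)
        annotated, _ = filter_bcr([t.full_sequence for t in templates], germline)
        graph = sq.build_network(annotated)
        clones = sq.define_clones(graph, annotated)
        assert len(clones) == k
        assert sum(c.total_reads for c in clones) == 40


class TestRenyiIndex:
    def test_single_clone_zero(self):
        for alpha in (0.5, 1.0, 2.0, 5.0):
            assert renyi_index([10], alpha) == 0.0

    def test_uniform_clones_log_k(self):
        for k in (2, 7, 100):
            for alpha in (0.5, 1.0, 2.0):
                assert renyi_index([3] * k, alpha) == pytest.approx(math.log(k))

    def test_alpha_to_one_shannon_limit(self, rng):
        w = rng.random(50)
        shannon = renyi_index(w, 1.0)
        assert abs(renyi_index(w, 1.0 + 1e-7) - shannon) < 1e-5

    def test_diversification_index_uniform(self):
        reads = {c: [f"s{c}_{u}" for u in range(3)] for c in range(8)}
        got = sq.clonal_diversification_index(reads, depth=1000, repeats=5, alpha=2)
        assert got == pytest.approx(math.log(8))

    def test_read_level_unit(self):
        reads = {0: ["a"] * 50, 1: ["b"] * 50}
        got = sq.clonal_diversification_index(
            reads, depth=40, repeats=10, alpha=2, unit="reads", seed=0
        )
        assert 0 < got <= math.log(2) + 1e-12


class TestIntraclonalDiversity:
    def test_identical_methods_equal_means(self):
        reads = [f"s{i % 7}" for i in range(40)]
        res = sq.intraclonal_diversity({"a": reads, "b": reads}, seed=1)
        assert res["a"] == pytest.approx(res["b"])

    def test_single_unique_sequence_mean_one(self):
        res = sq.intraclonal_diversity({"a": ["x"] * 100, "b": ["x"] * 80}, seed=2)
        assert res["a"] == 1.0 and res["b"] == 1.0

    def test_occupancy_oracle_orders_methods(self):
        # A: 100 reads over 20 uniform uniques; B: 80 reads over 5 uniques
        a = [f"a{i % 20}" for i in range(100)]
        b = [f"b{i % 5}" for i in range(80)]
        res = sq.intraclonal_diversity({"A": a, "B": b}, frac=0.75, repeats=50, seed=3)
        d = int(0.75 * 80)

        def occupancy(n, k, d):
            per = n // k
            return k * (1 - math.comb(n - per, d) / math.comb(n, d))

        assert res["A"] > res["B"]
        assert res["A"] == pytest.approx(occupancy(100, 20, d), abs=0.8)
        assert res["B"] == pytest.approx(occupancy(80, 5, d), abs=0.3)

    def test_depth_below_one_skips_clone(self):
        assert sq.intraclonal_diversity({"a": ["x"], "b": ["y"]}, frac=0.75) is None


class TestShmStats:
    def test_all_unmutated(self):
        stats = shm_stats([bcr("ACGT", v_mm=0), bcr("ACGA", v_mm=1, abundance=3)])
        assert stats["prop_unmutated"] == 1.0  # within 1 bp counts as unmutated

    def test_two_mismatches_count_mutated(self):
        stats = shm_stats([bcr("ACGT", v_mm=2), bcr("ACGA", v_mm=0)])
        assert stats["prop_unmutated"] == 0.5

    def test_mean_cdr3_length_weighted(self):
        a = bcr("A", cdr3="AAATTT", abundance=3)  # 2 aa
        b = bcr("C", cdr3="AAATTTGGGCCC", abundance=1)  # 4 aa
        stats = shm_stats([a, b])
        assert stats["mean_cdr3_aa_length"] == pytest.approx((2 * 3 + 4) / 4)


class TestVizSubsample:
    def test_single_clone_subgraph(self):
        members = [bcr("AAAA", abundance=300), bcr("AAAT", abundance=300)]
        g = sq.build_network(members)
        clones = sq.define_clones(g, members)
        sub = viz_subsample(g, clones, n_bcrs=500, repeats=10, seed=4)
        assert set(sub.graph.nodes) <= {"AAAA", "AAAT"}
        total = sum(d["abundance"] for _, d in sub.graph.nodes(data=True))
        assert total == 500

    def test_fixed_seed_reproducible(self):
        members = [bcr(f"AAA{b}", abundance=10 + i) for i, b in enumerate("ACGT")]
        g = sq.build_network(members)
        clones = sq.define_clones(g, members)
        a = viz_subsample(g, clones, n_bcrs=20, repeats=10, seed=5)
        b = viz_subsample(g, clones, n_bcrs=20, repeats=10, seed=5)
        assert sorted(a.graph.nodes) == sorted(b.graph.nodes)
        assert {n: d["abundance"] for n, d in a.graph.nodes(data=True)} == {
            n: d["abundance"] for n, d in b.graph.nodes(data=True)
        }
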