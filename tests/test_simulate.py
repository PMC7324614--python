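import numpy as np
import pytest

import sumiseq as sq
from sumiseq.dna import revcomp
from sumiseq.simulate import (
    MALBAC_FWD,
    MALBAC_REV,
    amplicon_sequence,
    simulate_pcr2_and_sequencing,
    standard_amplify_counts,
    write_paired_fastq,
    write_truth,
)


class TestGenerateTemplates:
    def test_unique_synthetic_umis(self, germline):
        cfg = sq.SimulationConfig(n_templates=2, seed=1)
        templates = sq.generate_templates(cfg, germline)
        assert len(templates) == 2
        assert templates[0].synthetic_umi != templates[1].synthetic_umi

    def test_zero_shm_leaves_v_segment_germline(self, germline):
        cfg = sq.SimulationConfig(n_templates=10, shm_rate=0.0, seed=2)
        for t in sq.generate_templates(cfg, germline):
            assert t.full_sequence.startswith(germline[t.v_gene].sequence)
            assert t.full_sequence.endswith(germline[t.j_gene].sequence)
            assert t.shm_positions == []

    def test_umi_collisions_redrawn(self, germline):
        # birthday problem: 1000 draws from 4^8 would collide ~7.6 times in
        # expectation, so observing zero collisions shows active rejection
        n, space = 1000, 4**8
        expected_collisions = n * (n - 1) / 2 / space
        assert expected_collisions > 5
        cfg = sq.SimulationConfig(n_templates=n, synthetic_umi_length=8, seed=3)
        umis = [t.synthetic_umi for t in sq.generate_templates(cfg, germline)]
        assert len(set(umis)) == n

    def test_pool_fractions_allocate_molecule_counts(self, germline):
        cfg = sq.SimulationConfig(
            n_templates=10,
            template_pool_fractions=[0.5, 0.3, 0.2],
            synthetic_umi_length=0,
            seed=4,
        )
        templates = sq.generate_templates(cfg, germline)
        by_seq: dict[str, int] = {}
        for t in templates:
            by_seq[t.full_sequence] = by_seq.get(t.full_sequence, 0) + 1
        assert sorted(by_seq.values()) == [2, 3, 5]

    def test_empty_germline_fatal(self):
        with pytest.raises(ValueError):
            sq.generate_templates(
                sq.SimulationConfig(), sq.GermlineDB([])
            )

    def test_shm_records_positions(self, germline):
        cfg = sq.SimulationConfig(n_templates=30, shm_rate=0.02, seed=5)
        templates = sq.generate_templates(cfg, germline)
        assert any(t.shm_positions for t in templates)
        for t in templates:
            for pos, old, new in t.shm_positions:
                assert t.full_sequence[pos] == new and old != new


class TestPCR1:
    def test_deterministic_limit(self, germline):
        cfg = sq.SimulationConfig(
            n_templates=1, pcr1_cycles=5, priming_prob_per_cycle=1.0,
            loop_reamp_prob_per_cycle=0.0, seed=1,
        )
        templates = sq.generate_templates(cfg, germline)
        amps = sq.simulate_pcr1(templates, cfg)
        assert len(amps) == 5
        assert len({(a.fwd_umi, a.rev_umi) for a in amps}) == 5
        assert all(a.lineage == "template_primed" for a in amps)

    def test_linear_growth_exact(self, germline):
        cfg = sq.SimulationConfig(
            n_templates=17, pcr1_cycles=8, priming_prob_per_cycle=1.0,
            loop_reamp_prob_per_cycle=0.0, seed=2,
        )
        templates = sq.generate_templates(cfg, germline)
        assert len(sq.simulate_pcr1(templates, cfg)) == 8 * 17

    def test_loop_fraction_matches_recursion(self, germline):
        # expected amplicons per template follow a_t = a_{t-1} (1+q) + p,
        # of which c*p are template-primed; compare the Monte-Carlo mean
        # loop fraction against the closed-form value within 3 SE
        p, q, cycles, n = 1.0, 0.01, 20, 100
        a = 0.0
        for _ in range(cycles):
            a = a * (1 + q) + p
        expected_frac = (a - cycles * p) / a
        cfg = sq.SimulationConfig(
            n_templates=n, pcr1_cycles=cycles, priming_prob_per_cycle=p,
            loop_reamp_prob_per_cycle=q, seed=0,
        )
        fracs = []
        for s in range(200):
            rng = np.random.default_rng(1000 + s)
            amps = sq.simulate.pcr1_events(n, cfg, rng)
            loops = sum(a_.lineage == "loop_reamplified" for a_ in amps)
            fracs.append(loops / len(amps))
        mean = float(np.mean(fracs))
        se = float(np.std(fracs, ddof=1) / np.sqrt(len(fracs)))
        assert abs(mean - expected_frac) <= 3 * se


class TestPCR2AndSequencing:
    def test_exact_depth_and_conservation(self, noisy_sim):
        assert len(noisy_sim["reads"]) == noisy_sim["config"].sequencing_depth
        assert len(noisy_sim["truth"]) == len(noisy_sim["reads"])

    def test_error_free_reads_match_truth(self, clean_sim):
        cfg = clean_sim["config"]
        amp_of = {
            a_id: amplicon_sequence(
                clean_sim["templates"][amp.template_index], amp, cfg
            )
            for a_id, amp in enumerate(clean_sim["amplicons"])
        }
        by_pair = {
            (a.fwd_umi, a.rev_umi): amp_of[i]
            for i, a in enumerate(clean_sim["amplicons"])
        }
        truth_pairs = dict(
            zip(clean_sim["truth"].read_id,
                zip(clean_sim["truth"].fwd_umi, clean_sim["truth"].rev_umi))
        )
        for pair in clean_sim["reads"]:
            amp = by_pair[truth_pairs[pair.read_id]]
            assert pair.fwd_seq == amp[: cfg.read_length]
            assert pair.rev_seq == revcomp(amp)[: cfg.read_length]

    def test_substitution_rate_binomial(self, germline):
        e = 0.005
        cfg = sq.SimulationConfig(
            n_templates=1, pcr1_cycles=1, priming_prob_per_cycle=1.0,
            loop_reamp_prob_per_cycle=0.0, sequencing_depth=400,
            seq_error_rate=e, quality_pass_fraction=1.0, seed=9,
        )
        templates = sq.generate_templates(cfg, germline)
        rng = np.random.default_rng(9)
        amps = sq.simulate_pcr1(templates, cfg, rng)
        reads, _ = simulate_pcr2_and_sequencing(amps, templates, cfg, rng)
        amp = amplicon_sequence(templates[0], amps[0], cfg)
        fwd_true, rev_true = amp[: cfg.read_length], revcomp(amp)[: cfg.read_length]
        mism = bases = 0
        for p in reads:
            mism += sum(a != b for a, b in zip(p.fwd_seq, fwd_true))
            mism += sum(a != b for a, b in zip(p.rev_seq, rev_true))
            bases += len(p.fwd_seq) + len(p.rev_seq)
        assert bases >= 1e5
        tol = 3 * np.sqrt(e * (1 - e) / bases)
        assert abs(mism / bases - e) <= tol

    def test_primer_umi_to_synthetic_umi_bijection_when_q0_e0(self, germline):
        cfg = sq.SimulationConfig(
            n_templates=15, loop_reamp_prob_per_cycle=0.0, seq_error_rate=0.0,
            quality_pass_fraction=1.0, sequencing_depth=500, seed=13,
        )
        templates, amps, reads, truth = sq.simulate_sumi(cfg, germline)
        pair_to_template = {}
        for r in truth.itertuples():
            key = (r.fwd_umi, r.rev_umi)
            assert pair_to_template.setdefault(key, r.template_id) == r.template_id
        # every observed pair is one priming event (depth limits which
        # events get sequenced, so observed pairs are a subset)
        event_pairs = {
            (a.fwd_umi, a.rev_umi): templates[a.template_index].template_id
            for a in amps
        }
        assert len(event_pairs) == len(amps)
        for key, tid in pair_to_template.items():
            assert event_pairs[key] == tid


class TestStandardPCR:
    def test_doubling_limit(self, rng):
        counts = standard_amplify_counts(1, np.array([1.0]), 5, rng)
        assert counts[0] == 32  # 2**5, original included

    def test_no_primer_umis_in_truth(self, germline):
        cfg = sq.SimulationConfig(n_templates=10, sequencing_depth=300, seed=3)
        templates = sq.generate_templates(cfg, germline)
        reads, truth = sq.simulate_standard_pcr(templates, cfg, total_cycles=12)
        assert (truth.fwd_umi == "").all() and (truth.rev_umi == "").all()
        assert len(reads) == 300


class TestDeterminism:
    def test_byte_identical_outputs(self, germline, tmp_path):
        cfg = sq.SimulationConfig(n_templates=10, sequencing_depth=200, seed=42)
        outputs = []
        for d in ("a", "b"):
            _, _, reads, truth = sq.simulate_sumi(cfg, germline)
            r1, r2 = write_paired_fastq(tmp_path / d, reads)
            write_truth(tmp_path / d / "truth.tsv", truth)
            outputs.append(
                (r1.read_bytes(), r2.read_bytes(),
                 (tmp_path / d / "truth.tsv").read_bytes())
            )
        assert outputs[0] == outputs[1]


def test_malbac_tails_are_distinct_constants():
    assert len(MALBAC_FWD) == len(MALBAC_REV) == 27
    assert MALBAC_FWD != MALBAC_REV
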