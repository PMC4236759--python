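from __future__ import annotations

import pytest

from chillseq.read_processing import (Read, TrimConfig, count_reads,
                                      filter_small_rna, trim_adapter)
from chillseq.synthetic_data import SimulationConfig, simulate_reads

from oracles import brute_count_hits, brute_trim

ADAPTER = "TCGTATGCCGTCTTCTGCTTG"
CFG = TrimConfig(adapter=ADAPTER)


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestTrimAdapter:
    def test_full_adapter_occurrence_is_trimmed(self):
        read = Read("r1", "ACGTACGT" + ADAPTER[:10])
        cfg = TrimConfig(adapter=ADAPTER[:10])
        trimmed, found, length = trim_adapter(read, cfg)
        assert trimmed.sequence == "ACGTACGT"
        assert found and length == 10

    def test_six_nt_evidence_is_not_enough(self):
        # evidence must be longer than 6 nt
        read = Read("r1", "ACGTACGTACGTAA" + ADAPTER[:6] + "CAAC")
        trimmed, found, _ = trim_adapter(read, CFG)
        assert not found and trimmed.sequence == read.sequence

    def test_seven_nt_evidence_trims(self):
        read = Read("r1", "ACGTACGTACGTAA" + ADAPTER[:7])
        trimmed, found, length = trim_adapter(read, CFG)
        assert found and length == 7
        assert trimmed.sequence == "ACGTACGTACGTAA"

    def test_matches_substring_enumeration_oracle(self, rng):
        adapter = _rand_seq(rng, 20)
        cfg = TrimConfig(adapter=adapter)
        for _ in range(200):
            seq = _rand_seq(rng, 50)
            if rng.random() < 0.5:  # implant adaptor evidence
                k = int(rng.integers(4, 21))
                pos = int(rng.integers(0, 50 - k + 1))
                a0 = int(rng.integers(0, 20 - k + 1))
                seq = seq[:pos] + adapter[a0:a0 + k] + seq[pos + k:]
            read = Read("r", seq)
            got, found, length = trim_adapter(read, cfg)
            exp_seq, exp_found, exp_len = brute_trim(seq, adapter, 7)
            assert found == exp_found and length == exp_len
            if exp_seq:  # empty insert is represented by a placeholder
                assert got.sequence == exp_seq

    def test_idempotent(self, rng):
        for _ in range(50):
            seq = _rand_seq(rng, 40) + ADAPTER[: int(rng.integers(0, 21))]
            once, found, _ = trim_adapter(Read("r", seq), CFG)
            twice, found2, _ = trim_adapter(once, CFG)
            assert twice.sequence == once.sequence
            # re-trimming an already clean insert finds nothing
            if found:
                assert not found2

    def test_quality_is_truncated_with_sequence(self):
        read = Read("r1", "ACGT" + ADAPTER[:8], "IIII" + "#" * 8)
        trimmed, _, _ = trim_adapter(read, CFG)
        assert trimmed.quality == "IIII"

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            TrimConfig(adapter="")


class TestFilterSmallRna:
    def test_length_window_and_reasons(self):
        cfg = TrimConfig(adapter=ADAPTER, require_adapter=True)
        reads = [
            (Read("short", "A" * 16), True),
            (Read("ok", "A" * 21), True),
            (Read("long", "A" * 29), True),
            (Read("noad", "A" * 21), False),
            (Read("amb", "A" * 10 + "N" + "A" * 10), True),
        ]
        kept, tally = filter_small_rna(reads, cfg)
        assert [r.id for r in kept] == ["ok"]
        assert tally == {"too_short": 1, "too_long": 1, "no_adapter": 1,
                         "ambiguous_base": 1}

    def test_kept_plus_rejected_partitions_input(self, rng):
        cfg = TrimConfig(adapter=ADAPTER, require_adapter=True)
        reads = []
        for i in range(300):
            n = int(rng.integers(10, 35))
            seq = _rand_seq(rng, n)
            if rng.random() < 0.1:
                seq = seq[: n // 2] + "N" + seq[n // 2 + 1:]
            reads.append((Read(f"r{i}", seq), bool(rng.random() < 0.8)))
        kept, tally = filter_small_rna(reads, cfg)
        assert len(kept) + sum(tally.values()) == len(reads)
        # direct per-read enumeration of the keep rule
        expected_kept = sum(
            1 for r, ad in reads
            if ad and "N" not in r.sequence and 17 <= len(r) <= 28)
        assert len(kept) == expected_kept


class TestCountReads:
    TRANSCRIPTS = [
        ("t1", "ACGTACGTACGTACGTACGTACGTACGTACGT"),
        ("t2", "TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAA"),
    ]

    def test_exact_substring_counts_once(self):
        reads = [Read("r1", self.TRANSCRIPTS[0][1][3:24])]
        col = count_reads(reads, self.TRANSCRIPTS)
        assert col.counts["t1"] == 1.0 and col.counts["t2"] == 0.0
        assert col.mapped_reads == 1

    def test_two_substitutions_is_unmapped(self):
        sub = list(self.TRANSCRIPTS[0][1][3:24])
        sub[0] = "T" if sub[0] != "T" else "G"
        sub[5] = "T" if sub[5] != "T" else "G"
        col = count_reads([Read("r1", "".join(sub))], self.TRANSCRIPTS)
        assert col.mapped_reads == 0 and col.unmapped_reads == 1

    def test_fractional_multimapping_conserves_mass(self):
        shared = "ACGTACGTACGTACGTACGTA"
        transcripts = [("a", "TT" + shared + "GG"), ("b", "CC" + shared + "AA")]
        col = count_reads([Read("r1", shared)], transcripts)
        assert col.counts["a"] == 0.5 and col.counts["b"] == 0.5
        assert sum(col.counts.values()) == col.mapped_reads == 1

    def test_matches_occurrence_scan_oracle(self, rng):
        transcripts = [(f"t{i}", _rand_seq(rng, 60)) for i in range(5)]
        for _ in range(100):
            if rng.random() < 0.5:  # sample from a transcript, maybe mutate
                _, tseq = transcripts[int(rng.integers(0, 5))]
                start = int(rng.integers(0, 60 - 21))
                seq = list(tseq[start:start + 21])
                for _ in range(int(rng.integers(0, 3))):
                    seq[int(rng.integers(0, 21))] = _rand_seq(rng, 1)
                seq = "".join(seq)
            else:
                seq = _rand_seq(rng, 21)
            col = count_reads([Read("r", seq)], transcripts)
            expected = {tid for tid, tseq in transcripts
                        if brute_count_hits(seq, tseq, 1)}
            mapped = {tid for tid, c in col.counts.items() if c > 0}
            assert mapped == expected
            if expected:
                assert abs(sum(col.counts.values()) - 1.0) < 1e-12

    def test_duplicate_transcript_ids_rejected(self):
        with pytest.raises(ValueError):
            count_reads([], [("t1", "ACGT" * 8), ("t1", "TTTT" * 8)])


class TestSimulatedReads:
    def test_noise_free_inserts_recovered_exactly(self):
        cfg = SimulationConfig(n_reads=150)
        reads, truth = simulate_reads(cfg, seed=5)
        trim_cfg = TrimConfig(adapter=cfg.adapter)
        for read, row in zip(reads, truth.itertuples()):
            trimmed, found, _ = trim_adapter(read, trim_cfg)
            assert found == row.has_adapter
            if found:
                assert trimmed.sequence == row.insert
            else:
                assert trimmed.sequence == row.insert + cfg.adapter[:row.adapter_len]

    def test_short_adapter_evidence_marked_absent(self):
        cfg = SimulationConfig(n_reads=300)
        reads, truth = simulate_reads(cfg, seed=6)
        short = truth[truth["adapter_len"].between(1, 6)]
        assert len(short) > 0
        trim_cfg = TrimConfig(adapter=cfg.adapter)
        for idx in short.index:
            _, found, _ = trim_adapter(reads[idx], trim_cfg)
            assert not found
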