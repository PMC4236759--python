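from __future__ import annotations

import pytest

from chillseq._util import revcomp
from chillseq.condition_comparison import DESet
from chillseq.mirna_targeting import (TargetScoringConfig, align_site,
                                      find_anticorrelated_pairs, pair_penalty,
                                      predict_targets, target_map)
from chillseq.synthetic_data import SimulationConfig, simulate_sequences

from oracles import brute_align_score

CFG = TargetScoringConfig()


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestPairPenalty:
    @pytest.mark.parametrize(
        "m, t, pos, expected",
        [
            ("A", "U", 10, 0.0),   # Watson-Crick outside the seed
            ("A", "T", 10, 0.0),
            ("G", "U", 10, 0.5),   # wobble
            ("U", "G", 10, 0.5),   # wobble, other strand contributes the G
            ("A", "C", 4, 2.0),    # seed mismatch doubled
            ("G", "U", 5, 1.0),    # seed wobble doubled
            ("A", "C", 1, 1.0),    # position 1 is outside the 2-7 seed
            ("A", "C", 8, 1.0),    # position 8 is outside the seed
        ],
    )
    def test_scheme(self, m, t, pos, expected):
        assert pair_penalty(m, t, pos, CFG) == expected

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            pair_penalty("A", "X", 3, CFG)


class TestAlignSite:
    MIRNA = "TGGAGCTCCCTTCATTCCAAT"

    def test_perfect_complement_scores_zero(self):
        aln, score = align_site(self.MIRNA, revcomp(self.MIRNA), CFG)
        assert score == 0.0
        assert set(aln[1]) == {"|"}

    def test_seed_wobble_plus_nonseed_mismatch(self):
        # miRNA position 5 (seed, G) paired with U -> 0.5 * 2 = 1.0;
        # position 12 mismatch -> 1.0; total 2.0
        m = self.MIRNA
        assert m[4] == "G" and not CFG.in_seed(12)
        window = list(revcomp(m))
        n = len(m)
        window[n - 5] = "T"    # G:U wobble at miRNA position 5
        window[n - 12] = m[11]  # same-base mismatch at position 12
        _, score = align_site(m, "".join(window), CFG)
        assert score == 2.0

    def test_t_u_representation_invariance(self, rng):
        m = _rand_seq(rng, 21)
        w = _rand_seq(rng, 21)
        _, s_dna = align_site(m, w, CFG)
        _, s_rna = align_site(m.replace("T", "U"), w.replace("T", "U"), CFG)
        assert s_dna == s_rna

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(120):
            n = int(rng.integers(17, 25))
            m = _rand_seq(rng, n)
            delta = int(rng.integers(-2, 3))
            if rng.random() < 0.5:
                w = _rand_seq(rng, n + delta)
            else:  # near-complement with a few mutations
                w = list(revcomp(m))
                for _ in range(int(rng.integers(0, 5))):
                    w[int(rng.integers(0, n))] = _rand_seq(rng, 1)
                w = "".join(w)[: n + delta] if delta <= 0 else \
                    "".join(w) + _rand_seq(rng, delta)
            _, got = align_site(m, w, CFG)
            assert got == pytest.approx(brute_align_score(m, w))

    def test_added_mismatch_never_lowers_score(self, rng):
        for _ in range(30):
            m = _rand_seq(rng, 21)
            w = list(revcomp(m))
            _, before = align_site(m, "".join(w), CFG)
            i = int(rng.integers(0, 21))
            w[i] = m[20 - i]  # break the pair at that position
            _, after = align_site(m, "".join(w), CFG)
            assert after >= before

    def test_incompatible_window_length_rejected(self):
        with pytest.raises(ValueError):
            align_site(self.MIRNA, revcomp(self.MIRNA) + "ACGTA", CFG)


class TestPredictTargets:
    def test_embedded_perfect_complement_found_with_coordinates(self, rng):
        m = _rand_seq(rng, 21)
        flank5, flank3 = _rand_seq(rng, 40), _rand_seq(rng, 39)
        tx = flank5 + revcomp(m) + flank3
        sites = predict_targets({"mir1": m}, {"tx1": tx}, CFG)
        exact = [s for s in sites if s.score == 0.0]
        assert len(exact) == 1
        assert (exact[0].start, exact[0].end) == (41, 61)

    def test_above_cutoff_site_absent(self):
        cfg = SimulationConfig(n_mirnas=2, n_transcripts=2,
                               planted_site_scores=(4.5,), n_planted_sites=1,
                               planted_above_cutoff_score=None)
        mirnas, transcripts, truth = simulate_sequences(cfg, seed=11)
        assert list(truth.sites["score"]) == [4.5]
        sites = predict_targets(mirnas, transcripts, CFG)
        planted = truth.sites.iloc[0]
        assert not any(s.mirna_id == planted.mirna_id
                       and s.transcript_id == planted.transcript_id
                       and s.start == planted.start for s in sites)

    def test_planted_sites_recovered_at_exact_scores(self):
        cfg = SimulationConfig(n_mirnas=10, n_transcripts=10,
                               planted_above_cutoff_score=None)
        mirnas, transcripts, truth = simulate_sequences(cfg, seed=3)
        sites = predict_targets(mirnas, transcripts, CFG)
        found = {(s.mirna_id, s.transcript_id, s.start): s.score for s in sites}
        assert len(truth.sites) == 20
        for row in truth.sites.itertuples():
            key = (row.mirna_id, row.transcript_id, row.start)
            assert key in found
            assert found[key] == pytest.approx(row.score)

    def test_lowering_cutoff_never_adds_sites(self):
        cfg = SimulationConfig(n_mirnas=6, n_transcripts=6,
                               planted_site_scores=(0.0, 2.0, 4.0),
                               n_planted_sites=9,
                               planted_above_cutoff_score=None)
        mirnas, transcripts, _ = simulate_sequences(cfg, seed=8)
        loose = predict_targets(mirnas, transcripts,
                                TargetScoringConfig(score_cutoff=4.0))
        strict = predict_targets(mirnas, transcripts,
                                 TargetScoringConfig(score_cutoff=2.0))
        loose_keys = {(s.mirna_id, s.transcript_id, s.start) for s in loose}
        strict_keys = {(s.mirna_id, s.transcript_id, s.start) for s in strict}
        assert strict_keys <= loose_keys


class TestAntiCorrelatedPairs:
    def _sites(self, rng):
        m = _rand_seq(rng, 21)
        tx = _rand_seq(rng, 30) + revcomp(m) + _rand_seq(rng, 30)
        return predict_targets({"mir1": m}, {"g1": tx}, CFG)

    def test_opposite_directions_paired(self, rng):
        sites = self._sites(rng)
        mir = DESet("CA/NC", frozenset(["mir1"]), frozenset())
        gene = DESet("CA/NC", frozenset(), frozenset(["g1"]))
        pairs = find_anticorrelated_pairs(mir, gene, sites)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.mirna_status, p.target_status) == ("up", "down")

    def test_same_direction_not_paired(self, rng):
        sites = self._sites(rng)
        mir = DESet("CA/NC", frozenset(["mir1"]), frozenset())
        gene = DESet("CA/NC", frozenset(["g1"]), frozenset())
        assert find_anticorrelated_pairs(mir, gene, sites) == []

    def test_non_de_target_not_paired(self, rng):
        sites = self._sites(rng)
        mir = DESet("CA/NC", frozenset(["mir1"]), frozenset())
        gene = DESet("CA/NC", frozenset(), frozenset())
        assert find_anticorrelated_pairs(mir, gene, sites) == []

    def test_comparison_mismatch_rejected(self, rng):
        sites = self._sites(rng)
        mir = DESet("CA/NC", frozenset(["mir1"]), frozenset())
        gene = DESet("CS/NC", frozenset(), frozenset(["g1"]))
        with pytest.raises(ValueError):
            find_anticorrelated_pairs(mir, gene, sites)

    def test_target_map_collapses_sites(self, rng):
        m = _rand_seq(rng, 21)
        tx = (_rand_seq(rng, 20) + revcomp(m) + _rand_seq(rng, 40)
              + revcomp(m) + _rand_seq(rng, 20))
        sites = predict_targets({"mir1": m}, {"g1": tx}, CFG)
        assert len([s for s in sites if s.score == 0.0]) == 2
        assert target_map(sites) == {"mir1": {"g1"}}
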