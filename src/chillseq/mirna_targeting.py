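"""Penalty-scored plant miRNA target prediction and anti-correlation pairing.

A candidate target site is scored by the total penalty of the best
antiparallel alignment of the miRNA against the site: 0 for a Watson-Crick
pair, 0.5 for a G:U wobble, 1 for a mismatch or for an inserted/deleted
base, with every penalty doubled when the involved miRNA position lies in
the seed region (positions 2-7 from the miRNA 5' end). Sites whose best
alignment score is no greater than the cutoff (default 4) are retained as
putative targets.

The alignment is a global dynamic program of the full miRNA against a
candidate window of the transcript, allowing at most ``max_indels`` gaps
(default 2). Transcripts are scanned with a vectorized semi-global pass
that finds every position where some window could score within the cutoff;
exact window alignments are then recomputed only there.

A predicted target becomes an *anti-correlated pair* when, in a given
condition comparison, both the miRNA and the target mRNA are differentially
expressed in opposite directions — the expression signature expected of
miRNA-guided cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import VALID_BASES, normalize_rna
from .condition_comparison import DESet

__all__ = [
    "TargetScoringConfig",
    "TargetSite",
    "AntiCorrelatedPair",
    "pair_penalty",
    "align_site",
    "predict_targets",
    "find_anticorrelated_pairs",
    "target_map",
]

_EPS = 1e-9

# base codes for vectorized penalty lookup
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class TargetScoringConfig:
    """Penalties and cutoff of the target-site scoring scheme."""

    mismatch_penalty: float = 1.0
    indel_penalty: float = 1.0
    wobble_penalty: float = 0.5
    seed_start: int = 2
    seed_end: int = 7
    seed_multiplier: float = 2.0
    score_cutoff: float = 4.0
    max_indels: int = 2

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.indel_penalty, self.wobble_penalty) < 0:
            raise ValueError("penalties must be non-negative")
        if not 1 <= self.seed_start <= self.seed_end:
            raise ValueError("require 1 <= seed_start <= seed_end")
        if self.score_cutoff < 0:
            raise ValueError("score_cutoff must be non-negative")
        if self.max_indels < 0:
            raise ValueError("max_indels must be non-negative")

    def in_seed(self, position: int) -> bool:
        return self.seed_start <= position <= self.seed_end

    def _mult(self, position: int) -> float:
        return self.seed_multiplier if self.in_seed(position) else 1.0

    def gap_penalty(self, mirna_position: int) -> float:
        """Per-base indel penalty keyed to a miRNA position.

        For a gap that skips miRNA base i, the key is i; for a bulged
        target base the key is the next miRNA position to be consumed.
        """
        return self.indel_penalty * self._mult(mirna_position)


@dataclass(frozen=True)
class TargetSite:
    """A retained miRNA binding site on a transcript.

    Coordinates are 1-based inclusive on the transcript sense strand; the
    alignment triple shows the miRNA 3'->5' over the target 5'->3'
    ('|' Watson-Crick, 'o' wobble, ' ' mismatch, '-' gap).
    """

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    score: float
    aln_mirna: str
    aln_symbols: str
    aln_target: str


@dataclass(frozen=True)
class AntiCorrelatedPair:
    mirna_id: str
    transcript_id: str
    comparison: str
    mirna_status: str
    target_status: str

    def __post_init__(self) -> None:
        assert {self.mirna_status, self.target_status} == {"up", "down"}


def _check_base(b: str) -> str:
    u = b.upper()
    if u not in VALID_BASES:
        raise ValueError(f"invalid base {b!r}")
    return "T" if u == "U" else u


def pair_penalty(mirna_base: str, target_base: str, mirna_position: int,
                 cfg: TargetScoringConfig = TargetScoringConfig()) -> float:
    """Penalty for pairing one miRNA base against one target base.

    Watson-Crick 0, G:U wobble (either strand contributing the G) 0.5,
    mismatch 1 — doubled at seed positions of the miRNA.
    """
    m = _check_base(mirna_base)
    t = _check_base(target_base)
    if {m, t} in ({"A", "T"}, {"G", "C"}):
        base = 0.0
    elif {m, t} == {"G", "T"}:
        base = cfg.wobble_penalty
    else:
        base = cfg.mismatch_penalty
    return base * cfg._mult(mirna_position)


def _penalty_matrix(cfg: TargetScoringConfig) -> np.ndarray:
    """4x4 base-pair penalty lookup (rows: miRNA base, cols: target base)."""
    pen = np.full((4, 4), cfg.mismatch_penalty)
    for a, b in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
        pen[_CODE[a], _CODE[b]] = 0.0
    pen[_CODE["G"], _CODE["T"]] = cfg.wobble_penalty
    pen[_CODE["T"], _CODE["G"]] = cfg.wobble_penalty
    return pen


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in seq], dtype=np.int8)


def align_site(mirna: str, target_window: str,
               cfg: TargetScoringConfig = TargetScoringConfig()
               ) -> tuple[tuple[str, str, str], float]:
    """Best global alignment of a miRNA against a candidate site window.

    ``target_window`` is the transcript subsequence 5'->3'; the miRNA pairs
    antiparallel to it (miRNA position 1 opposite the window's 3' end).
    Returns the alignment triple (miRNA 3'->5', symbols, target 5'->3')
    and the minimum total penalty, minimized over alignments with at most
    ``cfg.max_indels`` gaps.
    """
    m = normalize_rna(mirna)
    w = normalize_rna(target_window)
    if not set(m) <= set("ACGT") or not set(w) <= set("ACGT"):
        raise ValueError("sequences must be unambiguous nucleotides")
    n, L = len(m), len(w)
    if abs(L - n) > cfg.max_indels:
        raise ValueError(
            f"window length {L} incompatible with miRNA length {n} "
            f"and max_indels {cfg.max_indels}")
    r = w[::-1]  # r[j-1] pairs with miRNA position ~j
    G = cfg.max_indels
    INF = float("inf")
    # D[g][i][j]: best penalty aligning m[:i] with r[:j] using g gaps
    D = np.full((G + 1, n + 1, L + 1), INF)
    D[0, 0, 0] = 0.0
    for g in range(G + 1):
        for i in range(n + 1):
            for j in range(L + 1):
                if i == 0 and j == 0:
                    continue
                best = INF
                if i > 0 and j > 0:
                    best = D[g, i - 1, j - 1] + pair_penalty(m[i - 1], r[j - 1], i, cfg)
                if g > 0 and i > 0:
                    cand = D[g - 1, i - 1, j] + cfg.gap_penalty(i)
                    best = min(best, cand)
                if g > 0 and j > 0:
                    cand = D[g - 1, i, j - 1] + cfg.gap_penalty(min(i + 1, n))
                    best = min(best, cand)
                D[g, i, j] = best
    g_best = int(np.argmin(D[:, n, L]))
    score = float(D[g_best, n, L])
    # traceback
    mir_chars: list[str] = []
    sym_chars: list[str] = []
    tgt_chars: list[str] = []
    g, i, j = g_best, n, L
    while i > 0 or j > 0:
        here = D[g, i, j]
        if i > 0 and j > 0:
            p = pair_penalty(m[i - 1], r[j - 1], i, cfg)
            if abs(D[g, i - 1, j - 1] + p - here) < _EPS:
                mir_chars.append(m[i - 1])
                tgt_chars.append(r[j - 1])
                base = p / cfg._mult(i)
                sym_chars.append("|" if base == 0 else
                                 "o" if abs(base - cfg.wobble_penalty) < _EPS
                                 and cfg.wobble_penalty != cfg.mismatch_penalty
                                 else " ")
                i, j = i - 1, j - 1
                continue
        if g > 0 and i > 0 and abs(D[g - 1, i - 1, j] + cfg.gap_penalty(i) - here) < _EPS:
            mir_chars.append(m[i - 1])
            sym_chars.append(" ")
            tgt_chars.append("-")
            g, i = g - 1, i - 1
            continue
        assert g > 0 and j > 0
        mir_chars.append("-")
        sym_chars.append(" ")
        tgt_chars.append(r[j - 1])
        g, j = g - 1, j - 1
    # chars were collected miRNA 3'->5' (position n first): already the
    # requested top-strand order; the collected target chars follow r
    # reversed, i.e. the window 5'->3'.
    aln = ("".join(mir_chars), "".join(sym_chars), "".join(tgt_chars))
    return aln, score


def _scan_starts(mirna_codes: np.ndarray, rev_codes: np.ndarray,
                 pen: np.ndarray, cfg: TargetScoringConfig) -> np.ndarray:
    """Semi-global lower-bound scan of a miRNA along a reversed transcript.

    Returns, for every position j of the reversed transcript, a lower bound
    on the best window alignment score ending there (start free). Used only
    to prune; exact scores are recomputed per window.
    """
    n = mirna_codes.size
    L = rev_codes.size
    G = cfg.max_indels
    mult = np.array([cfg._mult(i) for i in range(1, n + 1)])
    INF = 1e18
    # prev[g][j]: row i-1; start free => row 0 all zero, for every g
    rows = np.zeros((G + 1, L + 1))
    for i in range(1, n + 1):
        p_row = pen[mirna_codes[i - 1], rev_codes] * mult[i - 1]
        new = np.full((G + 1, L + 1), INF)
        gap_m = cfg.gap_penalty(i)
        gap_t = cfg.gap_penalty(min(i + 1, n))
        for g in range(G + 1):
            diag = rows[g, :-1] + p_row
            new[g, 1:] = diag
            if g > 0:
                np.minimum(new[g], rows[g - 1] + gap_m, out=new[g])
                np.minimum(new[g, 1:], new[g - 1, :-1] + gap_t, out=new[g, 1:])
        rows = new
    return rows.min(axis=0)[1:]  # index j-1 -> end at reversed position j


def predict_targets(
    mirnas: Mapping[str, str] | Sequence[tuple[str, str]],
    transcripts: Mapping[str, str] | Sequence[tuple[str, str]],
    cfg: TargetScoringConfig = TargetScoringConfig(),
) -> list[TargetSite]:
    """Scan transcripts for miRNA target sites scoring within the cutoff.

    Every window of miRNA length +/- ``max_indels`` at every offset is
    considered; overlapping hits are merged keeping the best (lowest)
    score, ties going to the leftmost start. Output is ordered by
    (transcript, start, score, miRNA id).
    """
    mir_items = list(mirnas.items()) if isinstance(mirnas, Mapping) else list(mirnas)
    tr_items = (list(transcripts.items()) if isinstance(transcripts, Mapping)
                else list(transcripts))
    pen = _penalty_matrix(cfg)
    sites: list[TargetSite] = []
    for tid, tseq in tr_items:
        t = normalize_rna(tseq)
        L = len(t)
        rev = t[::-1]
        rev_codes = _encode(rev)
        for mid, mseq in mir_items:
            m = normalize_rna(mseq)
            n = len(m)
            if L < n - cfg.max_indels:
                continue
            bound = _scan_starts(_encode(m), rev_codes, pen, cfg)
            # reversed position j (1-based) corresponds to transcript start
            # s = L - j + 1 for a window extending rightwards from s
            cand_starts = sorted({L - (j + 1) + 1
                                  for j in np.nonzero(bound <= cfg.score_cutoff + _EPS)[0]})
            hits: list[TargetSite] = []
            for s in cand_starts:
                best: TargetSite | None = None
                # window lengths in order of parsimony (fewest indels first)
                for w_len in sorted(range(n - cfg.max_indels,
                                          n + cfg.max_indels + 1),
                                    key=lambda w: (abs(w - n), w)):
                    e = s + w_len - 1
                    if w_len <= 0 or e > L:
                        continue
                    aln, score = align_site(m, t[s - 1:e], cfg)
                    if score <= cfg.score_cutoff + _EPS:
                        if best is None or score < best.score - _EPS:
                            best = TargetSite(mid, tid, s, e, score, *aln)
                if best is not None:
                    hits.append(best)
            sites.extend(_merge_overlaps(hits))
    sites.sort(key=lambda s: (s.transcript_id, s.start, s.score, s.mirna_id))
    return sites


def _indels(site: TargetSite) -> int:
    return site.aln_mirna.count("-") + site.aln_target.count("-")


def _merge_overlaps(hits: list[TargetSite]) -> list[TargetSite]:
    """Keep the best-scoring site among mutually overlapping spans for one
    miRNA/transcript pair; score ties go to the more parsimonious
    alignment (fewer indels), then to the leftmost start."""
    kept: list[TargetSite] = []
    for site in sorted(hits, key=lambda s: (s.score, _indels(s), s.start, s.end)):
        if all(site.end < k.start or site.start > k.end for k in kept):
            kept.append(site)
    return kept


def target_map(sites: Iterable[TargetSite]) -> dict[str, set[str]]:
    """miRNA id -> set of predicted target transcript ids."""
    out: dict[str, set[str]] = {}
    for s in sites:
        out.setdefault(s.mirna_id, set()).add(s.transcript_id)
    return out


def find_anticorrelated_pairs(
    de_mirnas: DESet,
    de_mrnas: DESet,
    sites: Iterable[TargetSite],
    comparison: str | None = None,
) -> list[AntiCorrelatedPair]:
    """Emit (miRNA, target) pairs DE in opposite directions.

    One pair per (miRNA, transcript) regardless of how many sites link
    them; both DE sets must describe the same comparison.
    """
    if de_mirnas.comparison != de_mrnas.comparison:
        raise ValueError(
            f"comparison mismatch: {de_mirnas.comparison!r} vs "
            f"{de_mrnas.comparison!r}")
    label = comparison or de_mirnas.comparison
    pairs: dict[tuple[str, str], AntiCorrelatedPair] = {}
    for s in sites:
        key = (s.mirna_id, s.transcript_id)
        if key in pairs:
            continue
        ms = de_mirnas.status(s.mirna_id)
        ts = de_mrnas.status(s.transcript_id)
        if {ms, ts} == {"up", "down"}:
            pairs[key] = AntiCorrelatedPair(s.mirna_id, s.transcript_id,
                                            label, ms, ts)
    return [pairs[k] for k in sorted(pairs)]
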