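"""Read cleanup and toy-scale transcript counting.

Adaptor removal follows a recursive longest-substring rule: the longest
substring of the 3' sequencing adaptor that occurs anywhere in a read marks
the adaptor start, provided it is longer than a minimum evidence length
(default: more than 6 nt). Reads whose best adaptor evidence is shorter are
treated as having no adaptor. Small-RNA libraries are additionally filtered
by length (17-28 nt insert after trimming) and for ambiguous bases.

The counter here is a deliberately naive substitution-only matcher for toy
transcript sets; genome-scale alignment is out of scope and real-scale users
supply count tables directly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._util import VALID_DNA

__all__ = [
    "Read",
    "TrimConfig",
    "CountingConfig",
    "CountColumn",
    "trim_adapter",
    "filter_small_rna",
    "count_reads",
]


@dataclass(frozen=True)
class Read:
    """A single sequencing read; quality (Phred+33) is optional."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if not set(self.sequence.upper()) <= VALID_DNA:
            bad = set(self.sequence.upper()) - VALID_DNA
            raise ValueError(f"read {self.id!r}: invalid bases {sorted(bad)}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrimConfig:
    """Adaptor-trimming and length-filter parameters.

    min_match_len is the shortest adaptor substring accepted as evidence
    (7 means "longer than 6 nt"). max_read_len and require_adapter apply to
    small-RNA libraries only. low_quality_fraction/low_quality_phred define
    the low-quality read filter used when qualities are present: a read is
    low-quality when more than that fraction of its bases fall below the
    Phred cutoff.
    """

    adapter: str
    min_match_len: int = 7
    min_read_len: int = 17
    max_read_len: int = 28
    require_adapter: bool = False
    low_quality_fraction: float = 0.10
    low_quality_phred: int = 20

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if not 0 < self.min_match_len <= len(self.adapter):
            raise ValueError("require 0 < min_match_len <= len(adapter)")
        if not 0 < self.min_read_len <= self.max_read_len:
            raise ValueError("require 0 < min_read_len <= max_read_len")


@dataclass(frozen=True)
class CountingConfig:
    max_mismatch: int = 1
    multimap_policy: str = "fractional"  # fractional | all | discard

    def __post_init__(self) -> None:
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if self.multimap_policy not in ("fractional", "all", "discard"):
            raise ValueError(f"unknown multimap_policy {self.multimap_policy!r}")


@dataclass
class CountColumn:
    """One library's raw counts against a transcript set."""

    counts: dict[str, float]
    mapped_reads: float
    unmapped_reads: int = 0
    multimapped_reads: int = 0


def _longest_adapter_match(seq: str, adapter: str,
                           min_len: int) -> tuple[int, int] | None:
    """(position, length) of the leftmost occurrence of the longest adaptor
    substring of at least ``min_len`` found in ``seq``, or None."""
    for length in range(min(len(adapter), len(seq)), min_len - 1, -1):
        best_pos: int | None = None
        for start in range(len(adapter) - length + 1):
            pos = seq.find(adapter[start:start + length])
            if pos != -1 and (best_pos is None or pos < best_pos):
                best_pos = pos
        if best_pos is not None:
            return best_pos, length
    return None


def trim_adapter(read: Read, cfg: TrimConfig) -> tuple[Read, bool, int]:
    """Trim the 3' adaptor from a read by recursive longest-substring search.

    Each round finds the longest substring of the adaptor occurring in the
    read; if its length reaches ``cfg.min_match_len`` the read is truncated
    at the leftmost start of that longest occurrence, and the search
    recurses on the remainder until no evidence is left (which makes the
    operation idempotent). Returns the (possibly trimmed) read, whether
    adaptor evidence was found, and the first (longest) evidence length.
    """
    adapter = cfg.adapter.upper()
    seq = read.sequence
    first_len = 0
    while True:
        hit = _longest_adapter_match(seq.upper(), adapter, cfg.min_match_len)
        if hit is None:
            break
        pos, length = hit
        if first_len == 0:
            first_len = length
        seq = seq[:pos]
    if first_len == 0:
        return read, False, 0
    if not seq:
        # Pure-adaptor read: the insert is empty. Reads must carry a
        # sequence, so stand in a single N; length/ambiguity filters
        # reject it downstream.
        trimmed = Read(read.id, "N", "!" if read.quality else None)
    else:
        trimmed = Read(read.id, seq,
                       read.quality[:len(seq)] if read.quality else None)
    return trimmed, True, first_len


def _is_low_quality(read: Read, cfg: TrimConfig) -> bool:
    if read.quality is None:
        return False
    below = sum(1 for q in read.quality if ord(q) - 33 < cfg.low_quality_phred)
    return below / len(read.quality) > cfg.low_quality_fraction


def filter_small_rna(
    reads: Iterable[tuple[Read, bool]], cfg: TrimConfig
) -> tuple[list[Read], Counter]:
    """Apply the small-RNA qualification rules to trimmed reads.

    ``reads`` are (trimmed read, adapter_found) pairs as produced by
    :func:`trim_adapter`. Rejection reasons partition the rejected reads and
    are checked in a fixed order: no_adapter, low_quality, ambiguous_base,
    too_short, too_long.
    """
    kept: list[Read] = []
    tally: Counter = Counter()
    for read, adapter_found in reads:
        if cfg.require_adapter and not adapter_found:
            tally["no_adapter"] += 1
        elif _is_low_quality(read, cfg):
            tally["low_quality"] += 1
        elif "N" in read.sequence.upper():
            tally["ambiguous_base"] += 1
        elif len(read) < cfg.min_read_len:
            tally["too_short"] += 1
        elif len(read) > cfg.max_read_len:
            tally["too_long"] += 1
        else:
            kept.append(read)
    return kept, tally


def _occurrence_hits(seq: str, transcript: np.ndarray, max_mismatch: int) -> bool:
    """True when ``seq`` occurs in ``transcript`` (byte array) within
    ``max_mismatch`` substitutions, sense strand only."""
    n = len(seq)
    if n > transcript.size:
        return False
    q = np.frombuffer(seq.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(transcript, n)
    mism = (windows != q).sum(axis=1)
    return bool((mism <= max_mismatch).any())


def count_reads(
    reads: Sequence[Read],
    transcripts: Sequence[tuple[str, str]],
    cfg: CountingConfig = CountingConfig(),
) -> CountColumn:
    """Count qualified reads against a toy transcript set.

    A read is assigned to every transcript containing a sense-strand
    occurrence of it within ``max_mismatch`` substitutions (no indels).
    Multi-mapped reads are split fractionally, duplicated, or discarded per
    policy; with the fractional policy total count mass equals the number of
    mapped reads.
    """
    if not transcripts:
        raise ValueError("transcript set must be non-empty")
    ids = [tid for tid, _ in transcripts]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids")
    arrays = [
        (tid, np.frombuffer(seq.upper().encode(), dtype=np.uint8))
        for tid, seq in transcripts
    ]
    counts: dict[str, float] = {tid: 0.0 for tid in ids}
    mapped = 0.0
    unmapped = 0
    multi = 0
    for read in reads:
        seq = read.sequence.upper()
        hits = [tid for tid, arr in arrays if _occurrence_hits(seq, arr, cfg.max_mismatch)]
        if not hits:
            unmapped += 1
            continue
        if len(hits) > 1:
            multi += 1
            if cfg.multimap_policy == "discard":
                unmapped += 1
                continue
            if cfg.multimap_policy == "all":
                for tid in hits:
                    counts[tid] += 1.0
                mapped += 1
                continue
        share = 1.0 / len(hits)
        for tid in hits:
            counts[tid] += share
        mapped += 1
    return CountColumn(counts=counts, mapped_reads=mapped,
                       unmapped_reads=unmapped, multimapped_reads=multi)
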