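"""Independent brute-force oracles used to validate the fast paths.

Each oracle re-derives its result by exhaustive enumeration or direct
summation, sharing no code with the implementation it checks.
"""

from __future__ import annotations

from math import inf, lgamma


def _brute_trim_once(read: str, adapter: str, min_match: int):
    read_u, adapter_u = read.upper(), adapter.upper()
    for length in range(len(adapter_u), min_match - 1, -1):
        positions = []
        for a_start in range(len(adapter_u) - length + 1):
            sub = adapter_u[a_start:a_start + length]
            for r_start in range(len(read_u) - length + 1):
                if read_u[r_start:r_start + length] == sub:
                    positions.append(r_start)
        if positions:
            return read[:min(positions)], True, length
    return read, False, 0


def brute_trim(read: str, adapter: str, min_match: int) -> tuple[str, bool, int]:
    """Enumerate every adapter substring (longest first, leftmost first)
    against the read; truncate and repeat until no evidence remains."""
    seq, found, first_len = _brute_trim_once(read, adapter, min_match)
    while found:
        nxt, again, _ = _brute_trim_once(seq, adapter, min_match)
        if not again:
            break
        seq = nxt
    return seq, first_len > 0, first_len


_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


def _pair_pen(m: str, t: str, pos: int, seed=(2, 7), wobble=0.5, mism=1.0,
              mult=2.0) -> float:
    base = 0.0 if (m, t) in _WC else wobble if (m, t) in _WOBBLE else mism
    return base * (mult if seed[0] <= pos <= seed[1] else 1.0)


def brute_align_score(mirna: str, window: str, max_indels: int = 2,
                      indel: float = 1.0, seed=(2, 7), mult=2.0) -> float:
    """Minimum penalty over all global alignments with <= max_indels gaps,
    by plain recursion over the reversed window.

    Gap doubling: a skipped miRNA base keys its own position; a bulged
    target base keys the next miRNA position to be consumed.
    """
    m = mirna.upper().replace("U", "T")
    r = window.upper().replace("U", "T")[::-1]
    n, L = len(m), len(r)

    def go(i: int, j: int, gaps: int) -> float:
        if i == n and j == L:
            return 0.0
        best = inf
        if i < n and j < L:
            best = _pair_pen(m[i], r[j], i + 1, seed=seed, mult=mult) \
                + go(i + 1, j + 1, gaps)
        if gaps < max_indels:
            if i < n:  # skip miRNA base i+1
                s = seed[0] <= i + 1 <= seed[1]
                best = min(best, indel * (mult if s else 1.0)
                           + go(i + 1, j, gaps + 1))
            if j < L:  # bulged target base; next miRNA position is i+1
                key = min(i + 1, n)
                s = seed[0] <= key <= seed[1]
                best = min(best, indel * (mult if s else 1.0)
                           + go(i, j + 1, gaps + 1))
        return best

    return go(0, 0, 0)


def hypergeom_tail_sum(k: int, m: int, n: int, M: int) -> float:
    """P(X >= k) by direct log-space summation of the hypergeometric pmf."""

    def log_c(a: int, b: int) -> float:
        if b < 0 or b > a:
            return -inf
        return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)

    total = 0.0
    for i in range(k, min(m, n) + 1):
        lp = log_c(n, i) + log_c(M - n, m - i) - log_c(M, m)
        if lp > -inf:
            total += pow(2.718281828459045, lp)
    return min(total, 1.0)


def brute_count_hits(read: str, transcript: str, max_mismatch: int) -> bool:
    """Occurrence scan: does the read occur in the transcript (sense) with
    at most max_mismatch substitutions?"""
    r, t = read.upper(), transcript.upper()
    for start in range(len(t) - len(r) + 1):
        mism = sum(1 for a, b in zip(r, t[start:start + len(r)]) if a != b)
        if mism <= max_mismatch:
            return True
    return False
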