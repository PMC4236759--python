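"""GO term over-representation by the hypergeometric upper tail with BH FDR.

For a selected gene set of size m drawn from a universe of M genes, of
which n carry a term t, the enrichment p-value is P(X >= k) where k is the
observed overlap and X is hypergeometric — equivalently a one-sided
Fisher's exact test on the 2x2 table. Adjusted values use the
Benjamini-Hochberg step-up procedure across all tested terms.

Annotation here is flat term-to-gene: no GO-graph propagation to ancestor
terms is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "Annotation",
    "EnrichmentRecord",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
]


@dataclass
class Annotation:
    """Flat term -> gene mapping over a fixed gene universe."""

    term_to_genes: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        clean = {}
        for term, genes in self.term_to_genes.items():
            genes = frozenset(genes)
            outside = genes - self.universe
            if outside:
                raise ValueError(
                    f"term {term!r} annotates genes outside the universe: "
                    f"{sorted(outside)[:5]}")
            clean[term] = genes
        self.term_to_genes = clean

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   universe: Iterable[str] | None = None) -> "Annotation":
        """Build from (gene, term) pairs; universe defaults to all
        annotated genes."""
        mapping: dict[str, set[str]] = {}
        seen: set[str] = set()
        for gene, term in pairs:
            mapping.setdefault(term, set()).add(gene)
            seen.add(gene)
        uni = frozenset(universe) if universe is not None else frozenset(seen)
        return cls({t: frozenset(g) for t, g in mapping.items()}, uni)


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    k: int  # overlap
    m: int  # selected-set size
    n: int  # term-annotated genes in universe
    M: int  # universe size
    p: float
    fdr: float


def hypergeom_upper_tail(k: int, m: int, n: int, M: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, n, m), computed stably.

    k: observed overlap; m: selected genes; n: term-annotated genes;
    M: universe size.
    """
    if not (0 <= n <= M and 0 <= m <= M):
        raise ValueError(f"inconsistent parameters m={m}, n={n}, M={M}")
    if not 0 <= k <= min(m, n):
        raise ValueError(f"k={k} outside [0, min(m, n)={min(m, n)}]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, n, m))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(gene_set: Iterable[str], annotation: Annotation,
           min_term_size: int = 2) -> list[EnrichmentRecord]:
    """Test every sufficiently annotated term for over-representation.

    Genes outside the universe are dropped with a warning. Terms with
    fewer than ``min_term_size`` annotated genes, or no overlap with the
    selection, are not tested. Records are sorted by (p, term).
    """
    selected = set(gene_set)
    outside = selected - annotation.universe
    if outside:
        logger.warning("dropping %d genes outside the universe", len(outside))
        selected -= outside
    if not selected:
        raise ValueError("gene set is empty after universe filtering")
    M = len(annotation.universe)
    m = len(selected)
    tested: list[tuple[str, int, int]] = []
    for term in sorted(annotation.term_to_genes):
        genes = annotation.term_to_genes[term]
        n = len(genes)
        if n < min_term_size:
            continue
        k = len(selected & genes)
        if k == 0:
            continue
        tested.append((term, k, n))
    if not tested:
        return []
    pvals = [hypergeom_upper_tail(k, m, n, M) for _, k, n in tested]
    fdrs = bh_adjust(pvals)
    records = [
        EnrichmentRecord(term, k, m, n, M, p, float(f))
        for (term, k, n), p, f in zip(tested, pvals, fdrs)
    ]
    records.sort(key=lambda r: (r.p, r.term))
    return records


def records_to_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.term, r.k, r.m, r.n, r.M, r.p, r.fdr) for r in records],
        columns=["term", "k", "m", "n", "M", "p", "fdr"],
    )
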