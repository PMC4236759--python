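"""Set algebra and trajectory classification over DE calls.

The four-condition design (NC normal control, CA chilling acclimation at
14°C, CCA chilling after acclimation at 4°C, CS chilling shock at 4°C)
supports two kinds of cross-comparison analysis:

* *overlap partitions* between two DE sets (e.g. CA/NC vs CS/NC): genes
  common in the same direction, common in opposite directions, or specific
  to one comparison, with the derived percentages;
* *trajectory classification* across two successive comparisons (CA/NC then
  CCA/CA): a gene whose DE direction flips between them has *reversed*; one
  keeping its direction has *continued*.

The reversal statistics — what fraction of genes up- or down-regulated
during acclimation flip back under subsequent chilling — are the headline
quantities of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from ._util import percent

__all__ = [
    "DESet",
    "OverlapSummary",
    "TrajectoryCall",
    "overlap_partition",
    "classify_trajectory",
    "reversal_summary",
    "intersect_de_with_targets",
    "deset_from_table",
]


@dataclass(frozen=True)
class DESet:
    """Up- and down-regulated gene ids for one ordered comparison."""

    comparison: str  # e.g. "CA/NC"
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        both = self.up & self.down
        if both:
            raise ValueError(f"genes both up and down: {sorted(both)[:5]}")

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down

    def status(self, gene: str) -> str:
        if gene in self.up:
            return "up"
        if gene in self.down:
            return "down"
        return "not_de"


def deset_from_table(calls: pd.DataFrame, comparison: str) -> DESet:
    """Build a DESet from a call_de_table result (status column)."""
    return DESet(
        comparison,
        frozenset(calls.index[calls["status"] == "up"]),
        frozenset(calls.index[calls["status"] == "down"]),
    )


@dataclass
class OverlapSummary:
    """Partition of two DE sets and the derived percentages.

    ``common`` counts same-direction overlap; ``opposite`` counts genes DE
    in both comparisons with conflicting directions. Percentages are
    round-half-up to one decimal; the per-direction shares of the direction
    unions carry two decimals.
    """

    a_label: str
    b_label: str
    n_a: int
    n_b: int
    common_up: int
    common_down: int
    opposite: int
    a_specific: int
    b_specific: int
    union_up: int
    union_down: int

    @property
    def common(self) -> int:
        return self.common_up + self.common_down

    @property
    def common_total(self) -> int:
        """Genes DE in both comparisons, either direction pattern."""
        return self.common + self.opposite

    @property
    def pct_common_of_a(self) -> float:
        return percent(self.common_total, self.n_a)

    @property
    def pct_common_of_b(self) -> float:
        return percent(self.common_total, self.n_b)

    @property
    def pct_a_specific(self) -> float:
        return percent(self.a_specific, self.n_a)

    @property
    def pct_b_specific(self) -> float:
        return percent(self.b_specific, self.n_b)

    @property
    def pct_common_up_of_union(self) -> float:
        return percent(self.common_up, self.union_up, 2)

    @property
    def pct_common_down_of_union(self) -> float:
        return percent(self.common_down, self.union_down, 2)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_a", self.n_a), ("n_b", self.n_b),
            ("common_up", self.common_up), ("common_down", self.common_down),
            ("opposite", self.opposite),
            ("a_specific", self.a_specific), ("b_specific", self.b_specific),
            ("pct_common_of_a", self.pct_common_of_a),
            ("pct_common_of_b", self.pct_common_of_b),
            ("pct_a_specific", self.pct_a_specific),
            ("pct_b_specific", self.pct_b_specific),
            ("pct_common_up_of_union", self.pct_common_up_of_union),
            ("pct_common_down_of_union", self.pct_common_down_of_union),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def overlap_partition(a: DESet, b: DESet) -> OverlapSummary:
    """Partition two DE sets into common / opposite / specific genes."""
    common_up = len(a.up & b.up)
    common_down = len(a.down & b.down)
    opposite = len(a.up & b.down) + len(a.down & b.up)
    n_a = len(a.genes)
    n_b = len(b.genes)
    common_total = common_up + common_down + opposite
    return OverlapSummary(
        a_label=a.comparison, b_label=b.comparison,
        n_a=n_a, n_b=n_b,
        common_up=common_up, common_down=common_down, opposite=opposite,
        a_specific=n_a - common_total, b_specific=n_b - common_total,
        union_up=len(a.up | b.up), union_down=len(a.down | b.down),
    )


@dataclass(frozen=True)
class TrajectoryCall:
    gene: str
    first_status: str
    second_status: str
    klass: str  # reversed | continued | first_only | second_only | none


_OPPOSITE = {"up": "down", "down": "up"}


def classify_trajectory(first: DESet, second: DESet,
                        universe: Iterable[str] | None = None) -> list[TrajectoryCall]:
    """Classify each gene's path across two successive comparisons.

    The universe defaults to the union of DE genes of the two comparisons;
    every universe gene receives exactly one class.
    """
    if universe is None:
        genes = sorted(first.genes | second.genes)
    else:
        genes = sorted(set(universe))
    calls = []
    for g in genes:
        s1, s2 = first.status(g), second.status(g)
        if s1 != "not_de" and s2 != "not_de":
            klass = "reversed" if s2 == _OPPOSITE[s1] else "continued"
        elif s1 != "not_de":
            klass = "first_only"
        elif s2 != "not_de":
            klass = "second_only"
        else:
            klass = "none"
        calls.append(TrajectoryCall(g, s1, s2, klass))
    return calls


@dataclass
class ReversalSummary:
    """Per-direction reversal counts (keyed by first-comparison status)."""

    n_first: dict[str, int] = field(default_factory=dict)
    n_reversed: dict[str, int] = field(default_factory=dict)
    n_continued: dict[str, int] = field(default_factory=dict)
    n_dropped: dict[str, int] = field(default_factory=dict)

    @property
    def total_first(self) -> int:
        return sum(self.n_first.values())

    @property
    def total_reversed(self) -> int:
        return sum(self.n_reversed.values())

    def pct_reversed(self, direction: str | None = None) -> float:
        """Percentage of first-comparison DE genes (optionally of one
        direction) whose direction flipped in the second comparison."""
        if direction is None:
            return percent(self.total_reversed, self.total_first)
        return percent(self.n_reversed.get(direction, 0),
                       self.n_first.get(direction, 0))

    def pct_continued(self, direction: str | None = None) -> float:
        if direction is None:
            return percent(sum(self.n_continued.values()), self.total_first)
        return percent(self.n_continued.get(direction, 0),
                       self.n_first.get(direction, 0))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in sorted(self.n_first):
            rows.append((d, self.n_first[d], self.n_reversed.get(d, 0),
                         self.n_continued.get(d, 0), self.n_dropped.get(d, 0),
                         self.pct_reversed(d)))
        return pd.DataFrame(
            rows, columns=["first_status", "n_first", "n_reversed",
                           "n_continued", "n_dropped", "pct_reversed"])


def reversal_summary(calls: Iterable[TrajectoryCall]) -> ReversalSummary:
    """Tally reversal/continuation per first-comparison direction."""
    summ = ReversalSummary()
    for c in calls:
        if c.first_status == "not_de":
            continue
        d = c.first_status
        summ.n_first[d] = summ.n_first.get(d, 0) + 1
        if c.klass == "reversed":
            summ.n_reversed[d] = summ.n_reversed.get(d, 0) + 1
        elif c.klass == "continued":
            summ.n_continued[d] = summ.n_continued.get(d, 0) + 1
        else:
            summ.n_dropped[d] = summ.n_dropped.get(d, 0) + 1
    return summ


def intersect_de_with_targets(
    reversed_mrnas: Iterable[str],
    reversed_mirnas: Iterable[str],
    target_map: Mapping[str, Iterable[str]],
) -> list[tuple[str, str]]:
    """Link reversed miRNAs to reversed mRNAs they are predicted to target.

    Returns sorted (miRNA, mRNA) pairs where the miRNA is in the reversed
    miRNA set, the mRNA in the reversed mRNA set, and the mRNA is among the
    miRNA's predicted targets.
    """
    mr = set(reversed_mrnas)
    mi = set(reversed_mirnas)
    pairs = {
        (mirna, target)
        for mirna, targets in target_map.items()
        if mirna in mi
        for target in targets
        if target in mr
    }
    return sorted(pairs)
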