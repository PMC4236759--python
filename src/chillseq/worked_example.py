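"""Reference worked example: the chilling-study set sizes as input.

The four-condition cassava chilling design reports its comparison results
as set sizes: how many genes were DE in each comparison, how the CA/NC and
CS/NC sets overlap, and how many genes reversed direction between CA/NC
and CCA/CA. Those printed counts fully determine the derived percentages,
so they double as a machine-checkable worked example for the set-algebra
layer: this module reconstructs gene sets with exactly those sizes and
overlap structure, feeds them through :func:`overlap_partition` and
:func:`reversal_summary`, and returns every derived quantity.

The reconstruction uses synthetic gene ids — only set cardinalities
matter to the statistics computed here.
"""

from __future__ import annotations

from .condition_comparison import (DESet, classify_trajectory, overlap_partition,
                                   reversal_summary)
from ._util import percent

__all__ = [
    "mrna_overlap_desets",
    "mrna_trajectory_desets",
    "mirna_trajectory_desets",
    "mirna_overlap_desets",
    "cca_vs_cs_desets",
    "reference_summary",
]


def _ids(prefix: str, n: int, start: int = 0) -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(start, start + n)]


def mrna_overlap_desets() -> tuple[DESet, DESet]:
    """CA/NC vs CS/NC mRNA DE sets: 2,855 and 3,297 genes, sharing 1,041
    up- and 1,134 down-regulated genes with no opposite-direction overlap."""
    common_up = _ids("cu", 1041)
    common_down = _ids("cd", 1134)
    ca_only_up = _ids("au", 1507 - 1041)
    ca_only_down = _ids("ad", 1348 - 1134)
    cs_only_up = _ids("bu", 1703 - 1041)
    cs_only_down = _ids("bd", 1594 - 1134)
    ca = DESet("CA/NC", frozenset(common_up + ca_only_up),
               frozenset(common_down + ca_only_down))
    cs = DESet("CS/NC", frozenset(common_up + cs_only_up),
               frozenset(common_down + cs_only_down))
    return ca, cs


def mrna_trajectory_desets() -> tuple[DESet, DESet]:
    """CA/NC then CCA/CA: of 1,507 up-regulated genes 1,160 reverse and 3
    continue; of 1,348 down-regulated genes 641 reverse and 1 continues."""
    up = _ids("u", 1507)
    down = _ids("d", 1348)
    first = DESet("CA/NC", frozenset(up), frozenset(down))
    second = DESet(
        "CCA/CA",
        frozenset(up[1160:1163] + down[:641]),   # 3 continue up + 641 reverse
        frozenset(up[:1160] + down[641:642]),    # 1,160 reverse + 1 continues
    )
    return first, second


def mirna_trajectory_desets() -> tuple[DESet, DESet]:
    """81 DE miRNAs in CA/NC of which 16 up- and 14 down-regulated ones
    reverse in CCA/CA (30 in total)."""
    up = _ids("mu", 40)
    down = _ids("md", 41)
    first = DESet("CA/NC", frozenset(up), frozenset(down))
    second = DESet("CCA/CA", frozenset(down[:14]), frozenset(up[:16]))
    return first, second


def mirna_overlap_desets() -> tuple[DESet, DESet]:
    """CA/NC vs CS/NC miRNA DE sets: 17 of the 50 distinct up-regulated
    and 18 of the 57 distinct down-regulated miRNAs are shared."""
    common_up = _ids("xu", 17)
    common_down = _ids("xd", 18)
    ca = DESet("CA/NC", frozenset(common_up + _ids("yu", 30 - 17)),
               frozenset(common_down + _ids("yd", 25 - 18)))
    cs = DESet("CS/NC", frozenset(common_up + _ids("zu", 37 - 17)),
               frozenset(common_down + _ids("zd", 50 - 18)))
    return ca, cs


def cca_vs_cs_desets() -> tuple[DESet, DESet]:
    """CCA/NC vs CS/NC: 1,082 and 3,297 DE genes with 457 in both
    comparisons (446 same-direction, 11 opposite), leaving 625 CCA- and
    2,840 CS-specific genes."""
    common_up = _ids("ku", 223)
    common_down = _ids("kd", 223)
    opp_a_up = _ids("ou", 6)     # up in CCA, down in CS
    opp_a_down = _ids("od", 5)   # down in CCA, up in CS
    cca_only_up = _ids("pu", 312)
    cca_only_down = _ids("pd", 625 - 312)
    cs_only_up = _ids("qu", 1420)
    cs_only_down = _ids("qd", 2840 - 1420)
    cca = DESet("CCA/NC",
                frozenset(common_up + opp_a_up + cca_only_up),
                frozenset(common_down + opp_a_down + cca_only_down))
    cs = DESet("CS/NC",
               frozenset(common_up + opp_a_down + cs_only_up),
               frozenset(common_down + opp_a_up + cs_only_down))
    return cca, cs


def reference_summary() -> dict[str, dict[str, float]]:
    """Every derived percentage/count of the worked example, each computed
    by the set-algebra layer from the reconstructed sets.

    Returns a mapping of quantity name to ``{"value": ..., "n": ...}``
    where ``n`` is the denominator (or set size) the quantity refers to.
    """
    out: dict[str, dict[str, float]] = {}

    ca, cs = mrna_overlap_desets()
    ov = overlap_partition(ca, cs)
    out["mrna_common_pct_of_ca"] = {"value": ov.pct_common_of_a, "n": ov.n_a}
    out["mrna_common_pct_of_cs"] = {"value": ov.pct_common_of_b, "n": ov.n_b}
    out["mrna_common_down_pct_of_union"] = {
        "value": ov.pct_common_down_of_union, "n": ov.union_down}
    out["mrna_common_up_pct_of_union"] = {
        "value": ov.pct_common_up_of_union, "n": ov.union_up}

    first, second = mrna_trajectory_desets()
    rev = reversal_summary(classify_trajectory(first, second))
    out["up_reversed_pct"] = {"value": rev.pct_reversed("up"),
                              "n": rev.n_first["up"]}
    out["down_reversed_pct"] = {"value": rev.pct_reversed("down"),
                                "n": rev.n_first["down"]}
    out["reversed_genes_total"] = {"value": rev.total_reversed,
                                   "n": rev.total_first}

    mfirst, msecond = mirna_trajectory_desets()
    mrev = reversal_summary(classify_trajectory(mfirst, msecond))
    out["mirna_reversed_pct"] = {"value": mrev.pct_reversed(),
                                 "n": mrev.total_first}

    mca, mcs = mirna_overlap_desets()
    mov = overlap_partition(mca, mcs)
    out["mirna_common_up_pct_of_union"] = {
        "value": percent(mov.common_up, mov.union_up, 1), "n": mov.union_up}
    out["mirna_common_down_pct_of_union"] = {
        "value": percent(mov.common_down, mov.union_down, 1),
        "n": mov.union_down}

    cca, cs2 = cca_vs_cs_desets()
    ov2 = overlap_partition(cca, cs2)
    out["cca_specific_pct"] = {"value": ov2.pct_a_specific, "n": ov2.n_a}
    out["cs_specific_pct"] = {"value": ov2.pct_b_specific, "n": ov2.n_b}
    return out
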