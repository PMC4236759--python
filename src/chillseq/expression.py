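"""Expression calling and rule-based differential expression.

The analysis works on one pooled library per condition (no replicates), so
differential expression is called by explicit rules rather than a dispersion
model:

* a gene is *expressed* in a library when its CPM (counts per million mapped
  reads) is at least 10; below that the signal is treated as noise and the
  effective expression is 0;
* raw counts of expressed genes are made comparable across libraries by
  upper-quartile normalization (division by the 75th percentile of each
  library's nonzero counts, rescaled by the geometric mean of the factors so
  values stay count-like);
* a gene is *differentially expressed* between two conditions when either
  (1) it is expressed in both and its normalized counts differ by at least
  4-fold, or (2) it is not expressed (CPM < 10) in one condition and
  over-expressed (CPM > 40) in the other.

The same rules are applied to miRNA count tables. A 2^-ddCt helper converts
qRT-PCR cycle thresholds to relative expression for validation work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "DEConfig",
    "ExpressionProfile",
    "DECall",
    "compute_cpm",
    "flag_expressed",
    "upper_quartile_normalize",
    "build_profile",
    "call_de",
    "call_de_table",
    "qpcr_relative_expression",
    "QpcrRecord",
]


@dataclass
class CountTable:
    """Gene-by-library raw counts plus per-library mapped-read totals.

    Totals may exceed the column sums (reads can map outside annotated
    genes) but must be positive. Counts may be fractional under fractional
    multi-mapping.
    """

    counts: pd.DataFrame  # index: gene ids; columns: library ids
    totals: pd.Series  # index: library ids

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        self.totals = self.totals.astype(float)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [c for c in self.counts.columns if c not in self.totals.index]
        if missing:
            raise ValueError(f"libraries missing from totals: {missing}")
        self.totals = self.totals.loc[list(self.counts.columns)]
        if (self.totals <= 0).any():
            raise ValueError("mapped-read totals must be positive")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)


@dataclass(frozen=True)
class DEConfig:
    """Thresholds of the expressed/DE rules (CPM units; ratio for fold)."""

    cpm_expressed_min: float = 10.0
    cpm_overexpressed_min: float = 40.0
    fold_threshold: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.cpm_expressed_min < self.cpm_overexpressed_min:
            raise ValueError("require 0 < cpm_expressed_min < cpm_overexpressed_min")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")


@dataclass
class ExpressionProfile:
    """Per-gene per-library CPM, expressed flags and normalized counts."""

    cpm: pd.DataFrame
    expressed: pd.DataFrame  # boolean
    normalized: pd.DataFrame
    uq_factors: pd.Series

    def effective_expression(self) -> pd.DataFrame:
        """Normalized counts with non-expressed entries set to 0."""
        return self.normalized.where(self.expressed, 0.0)


@dataclass(frozen=True)
class DECall:
    gene: str
    comparison: tuple[str, str]  # (first, second); "up" = higher in first
    status: str  # up | down | not_de
    fold_change: float | None  # first/second normalized ratio when defined
    criterion: str  # fold | on_off | none

    def __post_init__(self) -> None:
        assert (self.status == "not_de") == (self.criterion == "none")


def compute_cpm(table: CountTable) -> pd.DataFrame:
    """CPM(g, lib) = raw(g, lib) / mapped_total(lib) * 1e6."""
    return table.counts.div(table.totals, axis=1) * 1e6


def flag_expressed(cpm: pd.DataFrame, cfg: DEConfig = DEConfig()) -> pd.DataFrame:
    """Expressed = CPM not less than the threshold (inclusive)."""
    return cpm >= cfg.cpm_expressed_min


def upper_quartile_normalize(table: CountTable) -> tuple[pd.DataFrame, pd.Series]:
    """Upper-quartile normalization of raw counts.

    Per library the scale factor is the 75th percentile (linear
    interpolation) of the counts of genes with count > 0. Normalized values
    are raw / factor, rescaled by the geometric mean of all factors to stay
    on a count-like scale; any positive rescaling constant yields identical
    DE calls.
    """
    factors = {}
    for lib in table.libraries:
        col = table.counts[lib].values
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"library {lib!r} has no nonzero counts")
        factors[lib] = float(np.percentile(nonzero, 75))
    uq = pd.Series(factors, name="uq_factor")
    scale = float(np.exp(np.mean(np.log(uq.values))))
    normalized = table.counts.div(uq, axis=1) * scale
    return normalized, uq


def build_profile(table: CountTable, cfg: DEConfig = DEConfig()) -> ExpressionProfile:
    """CPM, expressed flags and UQ-normalized counts in one pass."""
    cpm = compute_cpm(table)
    expressed = flag_expressed(cpm, cfg)
    normalized, uq = upper_quartile_normalize(table)
    return ExpressionProfile(cpm=cpm, expressed=expressed, normalized=normalized,
                             uq_factors=uq)


def _call_one(cpm_a: float, cpm_b: float, norm_a: float, norm_b: float,
              cfg: DEConfig) -> tuple[str, float | None, str]:
    expr_a = cpm_a >= cfg.cpm_expressed_min
    expr_b = cpm_b >= cfg.cpm_expressed_min
    fold = norm_a / norm_b if (norm_a > 0 and norm_b > 0) else None
    if expr_a and expr_b:
        hi, lo = max(norm_a, norm_b), min(norm_a, norm_b)
        ratio = np.inf if lo == 0 else hi / lo
        if ratio >= cfg.fold_threshold:
            status = "up" if norm_a > norm_b else "down"
            return status, fold, "fold"
        return "not_de", fold, "none"
    # on/off: not expressed on one side, over-expressed on the other
    if (not expr_a) and cpm_b > cfg.cpm_overexpressed_min:
        return "down", fold, "on_off"
    if (not expr_b) and cpm_a > cfg.cpm_overexpressed_min:
        return "up", fold, "on_off"
    return "not_de", None, "none"


def call_de(gene: str, comparison: tuple[str, str], profile: ExpressionProfile,
            cfg: DEConfig = DEConfig()) -> DECall:
    """Call one gene for an ordered (first, second) condition pair.

    "up" means higher in the first-named condition.
    """
    a, b = comparison
    for lib in (a, b):
        if lib not in profile.cpm.columns:
            raise KeyError(f"unknown condition {lib!r}")
    if gene not in profile.cpm.index:
        raise KeyError(f"unknown gene {gene!r}")
    status, fold, criterion = _call_one(
        float(profile.cpm.at[gene, a]),
        float(profile.cpm.at[gene, b]),
        float(profile.normalized.at[gene, a]),
        float(profile.normalized.at[gene, b]),
        cfg,
    )
    return DECall(gene, comparison, status, fold, criterion)


def call_de_table(profile: ExpressionProfile, comparison: tuple[str, str],
                  cfg: DEConfig = DEConfig()) -> pd.DataFrame:
    """Vectorized DE calls for every gene; columns: status, fold_change,
    criterion. Row order follows the profile's gene order."""
    a, b = comparison
    cpm_a = profile.cpm[a].values
    cpm_b = profile.cpm[b].values
    na = profile.normalized[a].values
    nb = profile.normalized[b].values
    expr_a = cpm_a >= cfg.cpm_expressed_min
    expr_b = cpm_b >= cfg.cpm_expressed_min

    both = expr_a & expr_b
    with np.errstate(divide="ignore", invalid="ignore"):
        hi = np.maximum(na, nb)
        lo = np.minimum(na, nb)
        ratio = np.where(lo > 0, hi / np.where(lo > 0, lo, 1.0), np.inf)
    fold_fires = both & (ratio >= cfg.fold_threshold)
    up_fold = fold_fires & (na > nb)
    down_fold = fold_fires & (nb > na)
    on_off_down = ~expr_a & (cpm_b > cfg.cpm_overexpressed_min)
    on_off_up = ~expr_b & (cpm_a > cfg.cpm_overexpressed_min)

    status = np.full(len(cpm_a), "not_de", dtype=object)
    criterion = np.full(len(cpm_a), "none", dtype=object)
    status[up_fold | on_off_up] = "up"
    status[down_fold | on_off_down] = "down"
    criterion[up_fold | down_fold] = "fold"
    criterion[on_off_up | on_off_down] = "on_off"

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where((na > 0) & (nb > 0), na / nb, np.nan)
    return pd.DataFrame(
        {"status": status, "fold_change": fc, "criterion": criterion},
        index=profile.cpm.index,
    )


@dataclass(frozen=True)
class QpcrRecord:
    """Cycle thresholds for one qRT-PCR relative-expression measurement."""

    ct_target_sample: float
    ct_reference_sample: float
    ct_target_control: float
    ct_reference_control: float
    ct_ntc: float | None = None

    def __post_init__(self) -> None:
        for v in (self.ct_target_sample, self.ct_reference_sample,
                  self.ct_target_control, self.ct_reference_control):
            if v <= 0:
                raise ValueError("CT values must be positive")


def qpcr_relative_expression(rec: QpcrRecord) -> float | str:
    """2^-ddCt relative expression; 'not expressed' when the target CT is
    not below the no-template control."""
    if rec.ct_ntc is not None and rec.ct_target_sample >= rec.ct_ntc:
        return "not expressed"
    d_sample = rec.ct_target_sample - rec.ct_reference_sample
    d_control = rec.ct_target_control - rec.ct_reference_control
    return float(2.0 ** -(d_sample - d_control))
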