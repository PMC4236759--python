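"""Synthetic study data with planted truth.

Emulates the statistical structure of a four-condition chilling experiment
(NC, CA, CCA, CS; one pooled library each) so the whole pipeline can be
exercised and scored against known ground truth:

* count tables with heavy-tailed baseline expression and negative-binomial
  library noise, with planted DE classes imposing the CA/NC vs CCA/CA sign
  structure (up or down during acclimation, then reversing, continuing, or
  holding) plus condition-specific classes for CS and CCA;
* miRNA and transcript sequences with target sites planted at exact,
  generator-verified alignment scores;
* small-RNA reads built from transcript fragments with 3' adaptor
  carry-over of varying length;
* flat GO-style annotation tables with one deliberately enriched term.

Every generator is a pure function of its configuration and seed.

Planted DE classes are placed on genes whose baseline expression exceeds a
configurable CPM floor (default 100) so that planted effects lie in the
regime the expressed/DE rules are designed for; with ``dispersion=0``
counts are the rounded expected values and recovery is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import revcomp
from .expression import CountTable
from .go_enrichment import Annotation
from .mirna_targeting import TargetScoringConfig, align_site
from .read_processing import Read, TrimConfig, trim_adapter

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "StudyBundle",
    "GenerationError",
    "simulate_counts",
    "simulate_sequences",
    "simulate_reads",
    "simulate_annotation",
    "simulate_study",
]

CONDITIONS = ("NC", "CA", "CCA", "CS")


class GenerationError(RuntimeError):
    """A requested planted structure could not be constructed."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    Fractions are of all genes and must sum to at most 1; ``planted_fold``
    is the mean ratio imposed by every planted DE class and must reach the
    DE fold threshold. Depths are mapped-read totals per library.
    """

    n_genes: int = 10_000
    n_mirnas: int = 120
    library_depths: dict[str, int] = field(
        default_factory=lambda: {c: 2_000_000 for c in CONDITIONS})
    dispersion: float = 0.05
    fraction_de_ca: float = 0.04
    fraction_reversed: float = 0.06
    fraction_continued: float = 0.002
    fraction_cs_specific: float = 0.03
    fraction_cca_specific: float = 0.02
    planted_fold: float = 8.0
    min_planted_cpm: float = 100.0
    baseline_log_mean: float = float(np.log(20.0))
    baseline_log_sd: float = 1.2
    # sequence layer
    mirna_len: int = 21
    n_transcripts: int = 60
    transcript_len: int = 500
    planted_site_scores: tuple[float, ...] = (0.0, 1.5, 3.0, 4.0)
    n_planted_sites: int = 20
    planted_above_cutoff_score: float | None = 4.5
    # reads layer
    adapter: str = "TCGTATGCCGTCTTCTGCTTG"
    n_reads: int = 500
    read_noise_rate: float = 0.0
    # annotation layer
    n_terms: int = 50
    planted_term_size: int = 100
    planted_term_overlap: float = 0.5

    def __post_init__(self) -> None:
        fracs = (self.fraction_de_ca, self.fraction_reversed,
                 self.fraction_continued, self.fraction_cs_specific,
                 self.fraction_cca_specific)
        if min(fracs) < 0 or sum(fracs) > 1:
            raise ValueError("class fractions must be >= 0 and sum to <= 1")
        if self.planted_fold < 1:
            raise ValueError("planted_fold must be >= 1")
        if any(d <= 0 for d in self.library_depths.values()):
            raise ValueError("library depths must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class TruthTable:
    """Planted ground truth; parts are filled by the generator that owns
    them (gene classes, target sites, enriched terms)."""

    genes: pd.DataFrame | None = None
    sites: pd.DataFrame | None = None
    terms: pd.DataFrame | None = None


# condition mean multipliers per class, as functions of the planted fold F
def _class_multipliers(F: float) -> dict[str, dict[str, float]]:
    return {
        "none": {"NC": 1, "CA": 1, "CCA": 1, "CS": 1},
        "de-up": {"NC": 1, "CA": F, "CCA": F, "CS": F},
        "de-down": {"NC": 1, "CA": 1 / F, "CCA": 1 / F, "CS": 1 / F},
        "reversed-up-down": {"NC": 1, "CA": F, "CCA": 1, "CS": F},
        "reversed-down-up": {"NC": 1, "CA": 1 / F, "CCA": 1, "CS": 1 / F},
        "continued-up": {"NC": 1, "CA": F, "CCA": F * F, "CS": F},
        "continued-down": {"NC": 1, "CA": 1 / F, "CCA": 1 / (F * F), "CS": 1 / F},
        "cs-specific-up": {"NC": 1, "CA": 1, "CCA": 1, "CS": F},
        "cs-specific-down": {"NC": 1, "CA": 1, "CCA": 1, "CS": 1 / F},
        "cca-specific-up": {"NC": 1, "CA": 1, "CCA": F, "CS": 1},
        "cca-specific-down": {"NC": 1, "CA": 1, "CCA": 1 / F, "CS": 1},
    }


def _assign_classes(cfg: SimulationConfig, rng: np.random.Generator,
                    n: int) -> np.ndarray:
    """Assign class labels to n items, splitting signed classes evenly."""
    labels = np.full(n, "none", dtype=object)
    order = rng.permutation(n)
    cursor = 0

    def take(count: int) -> np.ndarray:
        nonlocal cursor
        idx = order[cursor:cursor + count]
        cursor += count
        return idx

    def split(frac: float, up_label: str, down_label: str) -> None:
        count = int(round(frac * n))
        idx = take(count)
        half = count // 2
        labels[idx[:count - half]] = up_label
        labels[idx[count - half:]] = down_label

    split(cfg.fraction_de_ca, "de-up", "de-down")
    split(cfg.fraction_reversed, "reversed-up-down", "reversed-down-up")
    split(cfg.fraction_continued, "continued-up", "continued-down")
    split(cfg.fraction_cs_specific, "cs-specific-up", "cs-specific-down")
    split(cfg.fraction_cca_specific, "cca-specific-up", "cca-specific-down")
    return labels


def simulate_counts(cfg: SimulationConfig, seed: int,
                    ids: Sequence[str] | None = None,
                    prefix: str = "gene") -> tuple[CountTable, TruthTable]:
    """Four-library count table with planted DE/reversal structure.

    Baseline CPM is log-normal; planted classes get baselines resampled
    above ``min_planted_cpm`` so their effects are detectable by design.
    Counts are negative-binomial around condition means (``dispersion=0``
    gives the rounded expected counts). Returns the table and the per-gene
    truth (class label and planted fold per comparison).
    """
    rng = np.random.default_rng(seed)
    n = len(ids) if ids is not None else cfg.n_genes
    gene_ids = (list(ids) if ids is not None
                else [f"{prefix}{i:05d}" for i in range(1, n + 1)])
    labels = _assign_classes(cfg, rng, n)

    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, n))
    # Planted down-movers start high (>= the CPM floor) so their drop stays
    # measurable; planted up-movers start low (floor / fold) and rise into
    # the upper quartile as the down-movers leave it, which keeps the
    # per-library upper-quartile factors comparable — and mirrors regulation
    # toward a shared dynamic range.
    planted = labels != "none"
    uplift = np.exp(np.abs(rng.normal(0.0, 0.8, planted.sum())))
    up_classes = {"de-up", "reversed-up-down", "continued-up",
                  "cs-specific-up", "cca-specific-up"}
    is_up = np.array([lab in up_classes for lab in labels[planted]])
    floor = np.where(is_up, cfg.min_planted_cpm / cfg.planted_fold,
                     cfg.min_planted_cpm)
    baseline[planted] = floor * uplift

    mults = _class_multipliers(cfg.planted_fold)
    mult_matrix = np.array([[mults[lab][c] for c in CONDITIONS] for lab in labels])

    counts = {}
    for ci, cond in enumerate(CONDITIONS):
        depth = cfg.library_depths[cond]
        mean = baseline * mult_matrix[:, ci] * depth / 1e6
        if cfg.dispersion == 0:
            col = np.rint(mean)
        else:
            # NB as a gamma-Poisson mixture (shape 1/dispersion)
            shape = 1.0 / cfg.dispersion
            lam = rng.gamma(shape, mean / shape)
            col = rng.poisson(lam).astype(float)
        counts[cond] = col
    table = CountTable(
        counts=pd.DataFrame(counts, index=gene_ids),
        totals=pd.Series({c: float(cfg.library_depths[c]) for c in CONDITIONS}),
    )

    F = cfg.planted_fold
    fold_for = {lab: (m["CA"] / m["NC"], m["CCA"] / m["CA"], m["CS"] / m["NC"])
                for lab, m in mults.items()}
    truth = pd.DataFrame({
        "gene": gene_ids,
        "class": labels,
        "baseline_cpm": baseline,
        "fold_ca_nc": [fold_for[lab][0] for lab in labels],
        "fold_cca_ca": [fold_for[lab][1] for lab in labels],
        "fold_cs_nc": [fold_for[lab][2] for lab in labels],
    }).set_index("gene")
    return table, TruthTable(genes=truth)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _plant_mutations(mirna: str, score: float,
                     cfg_scoring: TargetScoringConfig,
                     rng: np.random.Generator) -> str:
    """Build a site window for ``mirna`` whose alignment score is exactly
    ``score`` by mutating a perfect reverse complement.

    Mutations: seed mismatch 2.0, non-seed mismatch 1.0, non-seed wobble
    0.5 (at a G/T miRNA position). A mismatch sets the target base equal to
    the miRNA base, which can never pair or wobble.
    """
    n = len(mirna)
    window = list(revcomp(mirna))
    seed_pos = [i for i in range(1, n + 1) if cfg_scoring.in_seed(i)]
    nonseed_pos = [i for i in range(1, n + 1) if not cfg_scoring.in_seed(i)]
    rng.shuffle(seed_pos)
    rng.shuffle(nonseed_pos)

    def set_target(pos: int, base: str) -> None:
        window[n - pos] = base  # miRNA pos i pairs window index n - i

    remaining = score
    if remaining != int(remaining * 2) / 2:
        raise GenerationError(f"score {score} not a multiple of 0.5")
    frac = remaining - int(remaining)
    if frac == 0.5:
        wobbleable = [i for i in nonseed_pos if mirna[i - 1] in "GT"]
        if not wobbleable:
            raise GenerationError("no non-seed G/T position for a wobble")
        pos = wobbleable[0]
        nonseed_pos.remove(pos)
        set_target(pos, "T" if mirna[pos - 1] == "G" else "G")
        remaining -= 0.5
    while remaining >= 2 and seed_pos:
        pos = seed_pos.pop()
        set_target(pos, mirna[pos - 1])
        remaining -= 2
    while remaining >= 1 and nonseed_pos:
        pos = nonseed_pos.pop()
        set_target(pos, mirna[pos - 1])
        remaining -= 1
    while remaining >= 1 and seed_pos:
        # fall back to seed wobbles (penalty 1) if non-seed ran out
        cand = [i for i in seed_pos if mirna[i - 1] in "GT"]
        if not cand:
            break
        pos = cand[0]
        seed_pos.remove(pos)
        set_target(pos, "T" if mirna[pos - 1] == "G" else "G")
        remaining -= 1
    if remaining != 0:
        raise GenerationError(
            f"could not decompose score {score} for miRNA {mirna}")
    return "".join(window)


def _best_overlapping_score(mirna: str, transcript: str, start: int,
                            end: int, scoring: TargetScoringConfig) -> float:
    """Minimum alignment score over every window overlapping [start, end]."""
    n = len(mirna)
    L = len(transcript)
    best = float("inf")
    for s in range(max(1, start - scoring.max_indels - 2),
                   min(end, L) + 1):
        for w in range(n - scoring.max_indels, n + scoring.max_indels + 1):
            e = s + w - 1
            if w <= 0 or e > L or e < start:
                continue
            _, sc = align_site(mirna, transcript[s - 1:e], scoring)
            best = min(best, sc)
    return best


def simulate_sequences(
    cfg: SimulationConfig, seed: int,
    mirna_ids: Sequence[str] | None = None,
    transcript_ids: Sequence[str] | None = None,
    site_plan: Sequence[tuple[str, str, float]] | None = None,
    scoring: TargetScoringConfig = TargetScoringConfig(),
) -> tuple[dict[str, str], dict[str, str], TruthTable]:
    """Random miRNA and transcript sequences with planted target sites.

    ``site_plan`` lists (miRNA id, transcript id, requested score); by
    default ``n_planted_sites`` sites cycle through
    ``planted_site_scores`` over the id lists round-robin, plus one
    above-cutoff control site when configured. Each planted window is
    re-scored with :func:`align_site` at generation time; a mismatch raises
    :class:`GenerationError`. Returns (miRNAs, transcripts, truth).
    """
    rng = np.random.default_rng(seed)
    mids = (list(mirna_ids) if mirna_ids is not None
            else [f"mir{i:03d}" for i in range(1, cfg.n_mirnas + 1)])
    tids = (list(transcript_ids) if transcript_ids is not None
            else [f"tx{i:03d}" for i in range(1, cfg.n_transcripts + 1)])
    mirnas = {mid: _random_seq(rng, cfg.mirna_len) for mid in mids}
    transcripts = {tid: _random_seq(rng, cfg.transcript_len) for tid in tids}

    if site_plan is None:
        scores = [cfg.planted_site_scores[i % len(cfg.planted_site_scores)]
                  for i in range(cfg.n_planted_sites)]
        if cfg.planted_above_cutoff_score is not None:
            scores.append(cfg.planted_above_cutoff_score)
        site_plan = [
            (mids[i % len(mids)], tids[i % len(tids)], s)
            for i, s in enumerate(scores)
        ]

    occupied: dict[str, list[tuple[int, int]]] = {tid: [] for tid in tids}
    rows = []
    for mid, tid, req_score in site_plan:
        mirna = mirnas[mid]
        n = len(mirna)
        placed = False
        for _ in range(50):
            window = _plant_mutations(mirna, req_score, scoring, rng)
            start = int(rng.integers(1, cfg.transcript_len - n))
            end = start + n - 1
            pad = scoring.max_indels + 2
            if any(start - pad <= e and end + pad >= s
                   for s, e in occupied[tid]):
                continue
            _, got = align_site(mirna, window, scoring)
            if abs(got - req_score) > 1e-9:
                continue
            t = transcripts[tid]
            candidate = t[:start - 1] + window + t[end:]
            # no overlapping window (any length, any nearby start) may
            # align strictly better than the planted score, or the site's
            # effective score would differ from the request
            if _best_overlapping_score(mirna, candidate, start, end,
                                       scoring) < req_score - 1e-9:
                continue
            transcripts[tid] = candidate
            occupied[tid].append((start, end))
            rows.append((mid, tid, start, end, req_score))
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"failed to plant a score-{req_score} site for {mid} on {tid}")
    truth_sites = pd.DataFrame(
        rows, columns=["mirna_id", "transcript_id", "start", "end", "score"])
    return mirnas, transcripts, TruthTable(sites=truth_sites)


def simulate_reads(
    cfg: SimulationConfig, seed: int,
    transcripts: dict[str, str] | None = None,
    min_match_len: int = 7,
) -> tuple[list[Read], pd.DataFrame]:
    """Small-RNA-style reads: transcript fragments (17-28 nt) followed by a
    3' adaptor prefix of random length (0 to full), with optional
    substitution noise on the insert.

    Each composed read is verified at generation time against the trimming
    rule itself: inserts whose sequence would create spurious adaptor
    evidence (or extend the real boundary match leftward) are resampled,
    so the recorded truth matches the rule exactly. Truth columns: read
    id, source transcript, insert, adapter_len, has_adapter (evidence >=
    min_match_len).
    """
    rng = np.random.default_rng(seed)
    if transcripts is None:
        transcripts = {f"tx{i:03d}": _random_seq(rng, cfg.transcript_len)
                       for i in range(1, cfg.n_transcripts + 1)}
    tids = sorted(transcripts)
    adapter = cfg.adapter.upper()
    trim_cfg = TrimConfig(adapter=adapter, min_match_len=min_match_len)
    reads: list[Read] = []
    rows = []
    for i in range(cfg.n_reads):
        rid = f"read{i + 1:05d}"
        for _ in range(100):
            tid = tids[int(rng.integers(0, len(tids)))]
            tseq = transcripts[tid]
            ins_len = int(rng.integers(17, 29))
            start = int(rng.integers(0, len(tseq) - ins_len + 1))
            insert = list(tseq[start:start + ins_len])
            if cfg.read_noise_rate > 0:
                for j in range(len(insert)):
                    if rng.random() < cfg.read_noise_rate:
                        insert[j] = "ACGT"[int(rng.integers(0, 4))]
            insert = "".join(insert)
            ad_len = int(rng.integers(0, len(adapter) + 1))
            seq = insert + adapter[:ad_len]
            trimmed, found, _ = trim_adapter(Read(rid, seq), trim_cfg)
            if found == (ad_len >= min_match_len) and (
                    not found or trimmed.sequence == insert):
                break
        else:
            raise GenerationError("could not sample a rule-consistent read")
        reads.append(Read(rid, seq, "I" * len(seq)))
        rows.append((rid, tid, insert, ad_len, ad_len >= min_match_len))
    truth = pd.DataFrame(
        rows, columns=["read_id", "transcript_id", "insert",
                       "adapter_len", "has_adapter"])
    return reads, truth


def simulate_annotation(
    cfg: SimulationConfig, seed: int,
    universe: Sequence[str],
    enriched_in: Sequence[str],
) -> tuple[Annotation, TruthTable]:
    """Flat annotation with one planted enriched term.

    The planted term (``TERM_PLANTED``) draws ``planted_term_overlap`` of
    its genes from ``enriched_in`` and the rest from the universe; the
    remaining ``n_terms - 1`` terms are uniform random draws.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    target_set = [g for g in enriched_in if g in set(universe)]
    if not target_set:
        raise GenerationError("enriched_in has no genes inside the universe")
    term_to_genes: dict[str, frozenset[str]] = {}
    rows = []
    n_from_set = min(int(round(cfg.planted_term_size * cfg.planted_term_overlap)),
                     len(target_set))
    chosen = list(rng.choice(target_set, size=n_from_set, replace=False))
    rest = [g for g in universe if g not in set(target_set)]
    n_rest = max(cfg.planted_term_size - n_from_set, 0)
    chosen += list(rng.choice(rest, size=n_rest, replace=False))
    term_to_genes["TERM_PLANTED"] = frozenset(chosen)
    rows.append(("TERM_PLANTED", True, len(chosen)))
    for i in range(1, cfg.n_terms):
        size = int(rng.integers(10, 201))
        genes = frozenset(rng.choice(universe, size=size, replace=False))
        term = f"TERM_{i:04d}"
        term_to_genes[term] = genes
        rows.append((term, False, size))
    annotation = Annotation(term_to_genes, frozenset(universe))
    truth = pd.DataFrame(rows, columns=["term", "enriched", "size"])
    return annotation, TruthTable(terms=truth)


@dataclass
class StudyBundle:
    """Everything one synthetic study run produces."""

    mrna_counts: CountTable
    mrna_truth: TruthTable
    mirna_counts: CountTable
    mirna_truth: TruthTable
    mirnas: dict[str, str]
    transcripts: dict[str, str]
    site_truth: TruthTable
    annotation: Annotation
    annotation_truth: TruthTable
    planted_pairs: list[tuple[str, str]]


def simulate_study(cfg: SimulationConfig, seed: int) -> StudyBundle:
    """Generate a coherent study: mRNA and miRNA count tables sharing the
    planted reversal structure, sequences whose planted sites link reversed
    miRNAs to reversed target genes (the anti-correlation truth), and an
    annotation enriched in the reversed genes.

    Derived seeds keep the layers independent but reproducible.
    """
    mrna_counts, mrna_truth = simulate_counts(cfg, seed, prefix="gene")
    # miRNA libraries carry proportionally more DE/reversal signal than the
    # mRNA side, mirroring small-RNA responsiveness to chilling
    mir_cfg = replace(cfg, n_genes=cfg.n_mirnas, fraction_de_ca=0.15,
                      fraction_reversed=0.20, fraction_continued=0.01,
                      fraction_cs_specific=0.05, fraction_cca_specific=0.05)
    mirna_counts, mirna_truth = simulate_counts(
        mir_cfg, (seed + 1) % 2**31, prefix="mir")

    g = mrna_truth.genes
    mi = mirna_truth.genes
    rev_up_mirnas = list(mi.index[mi["class"] == "reversed-up-down"])
    rev_down_mirnas = list(mi.index[mi["class"] == "reversed-down-up"])
    rev_up_genes = list(g.index[g["class"] == "reversed-up-down"])
    rev_down_genes = list(g.index[g["class"] == "reversed-down-up"])

    # anti-correlated planted pairs in the CA/NC comparison: miRNA and
    # target move in opposite directions
    pairs: list[tuple[str, str]] = []
    scores = list(cfg.planted_site_scores)
    for i, (mir, gene) in enumerate(
            list(zip(rev_up_mirnas, rev_down_genes))
            + list(zip(rev_down_mirnas, rev_up_genes))):
        if len(pairs) >= cfg.n_planted_sites:
            break
        pairs.append((mir, gene))

    # transcripts: the planted target genes plus unrelated decoys
    pair_targets = sorted({gene for _, gene in pairs})
    n_decoys = max(cfg.n_transcripts - len(pair_targets), 0)
    decoys = [gid for gid in g.index if gid not in set(pair_targets)][:n_decoys]
    transcript_ids = pair_targets + decoys

    site_plan = [(mir, gene, scores[i % len(scores)])
                 for i, (mir, gene) in enumerate(pairs)]
    if cfg.planted_above_cutoff_score is not None and decoys:
        site_plan.append((sorted(mi.index)[0], decoys[0],
                          cfg.planted_above_cutoff_score))
    mirnas, transcripts, site_truth = simulate_sequences(
        cfg, (seed + 2) % 2**31,
        mirna_ids=list(mi.index), transcript_ids=transcript_ids,
        site_plan=site_plan)

    reversed_genes = rev_up_genes + rev_down_genes
    annotation, ann_truth = simulate_annotation(
        cfg, (seed + 3) % 2**31, universe=list(g.index),
        enriched_in=reversed_genes)

    return StudyBundle(
        mrna_counts=mrna_counts, mrna_truth=mrna_truth,
        mirna_counts=mirna_counts, mirna_truth=mirna_truth,
        mirnas=mirnas, transcripts=transcripts, site_truth=site_truth,
        annotation=annotation, annotation_truth=ann_truth,
        planted_pairs=pairs)
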