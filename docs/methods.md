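# Methods

This note records the models, parameter choices and numerical conventions
behind `chillseq`, the assumptions they rest on, and what the synthetic
validation does and does not demonstrate.

## Study design assumed

Four conditions — NC (normal, 24°C), CA (chilling acclimation, 14°C), CCA
(chilling after acclimation, 4°C), CS (chilling shock, 4°C) — each
represented by a single pooled library for mRNA and for small RNA. There
are no replicates, so all differential-expression calling is rule-based;
dispersion-model methods (DESeq2/edgeR-style) are deliberately out of
scope. Comparisons are ordered pairs (first, second); "up" always means
higher in the first-named condition.

## Read processing

Adaptor trimming recursively searches for the longest substring of the 3'
adaptor occurring anywhere in the read; if its length is at least
`min_match_len` (default 7, i.e. evidence longer than 6 nt) the read is
truncated at the leftmost start of that longest occurrence and the search
repeats on the remainder until no evidence is left. The repeat makes the
operation idempotent; ties between equally long substrings at different
positions go to the leftmost (only position and length affect the result).
A read trimmed to nothing is represented by a single-N placeholder that
the downstream ambiguity/length filters reject.

Small-RNA qualification keeps reads with adaptor evidence (when required),
no ambiguous bases, and trimmed length within 17–28 nt, the gel-purified
size range. Rejection reasons are tallied in a fixed priority order
(no_adapter, low_quality, ambiguous_base, too_short, too_long) so the
tally partitions the rejected reads. The low-quality rule — more than 10%
of bases below Q20, applied only when qualities are present — is a
configurable stand-in: no specific definition exists for this design, and
the default is deliberately mild.

The toy read counter assigns a read to every transcript containing a
sense-strand occurrence within `max_mismatch` substitutions (0 or 1; no
indels, matching a `-v 1`-style alignment contract). Multi-mapped reads
are split fractionally by default, which conserves total mapped mass;
`all` and `discard` policies are selectable. This counter exists to make
the pipeline testable end to end at desk scale — genome-scale alignment is
explicitly not a goal, and real analyses enter at the count-table stage.

## Expression and differential expression

CPM uses the per-library mapped-read total supplied alongside the counts;
that total may exceed the column sum (reads mapping outside annotated
genes), and whether it counts genome- or transcript-mapped reads is the
caller's choice (genome-mapped assumed for the synthetic data).

Upper-quartile factors are the 75th percentile of each library's nonzero
counts, computed with linear interpolation (`numpy.percentile` default) —
the interpolation rule is fixed and documented because the method itself
leaves it open. After division, values are rescaled by the geometric mean
of the factors purely for interpretability; any positive constant yields
identical DE calls because the fold criterion is a ratio (asserted in
tests).

The two DE criteria are evaluated exactly as separated in their source:
criterion (1), the ≥ 4-fold change, uses UQ-normalized counts and applies
only when the gene is expressed (CPM ≥ 10) in both conditions; criterion
(2), on/off, uses raw CPM: below 10 on one side and strictly above 40 on
the other. Thresholds are inclusive where the wording is inclusive
("no less than 4 folds", "not less than 10") and strict where it is strict
("CPM > 40"). A gene expressed in neither condition is never DE. The same
rules and thresholds are applied to miRNA count tables (no separate rule
is defined for miRNAs; the thresholds are overridable in `DEConfig`).

qRT-PCR relative expression is 2^−ΔΔCt with ΔCt = Ct(target) −
Ct(reference) per sample; a target Ct at or above the no-template control
is reported as "not expressed".

## Overlap and reversal statistics

Two DE sets partition into common-same-direction (by direction),
common-opposite-direction, and set-specific genes. Printed percentages are
rounded half-up to one decimal (the convention that reproduces every
checkable reference value); the per-direction shares of the direction
unions carry two decimals. Trajectory classification compares CA/NC
against CCA/CA (not CCA/NC); the API takes explicit ordered pairs so the
contrast cannot be silently wrong. The universe for trajectory calls
defaults to the union of the two DE sets.

## miRNA target scoring

Penalties: mismatch and per-base indel 1, G:U wobble 0.5 (whichever strand
contributes the G), doubled when the involved miRNA position lies in the
seed (positions 2–7 from the 5' end; position 1 and positions beyond 7 are
single). The site score is the minimum-penalty *global* alignment of the
full miRNA against a candidate transcript window, antiparallel, computed
by dynamic programming over substitutions/wobbles/indels with at most
`max_indels` = 2 gaps per site. Three conventions the penalty table alone
does not determine, fixed here:

* indels are charged per base, not per gap opening;
* a gap that skips miRNA base i keys its seed-doubling to position i; a
  bulged target base keys to the next miRNA position to be consumed;
* overlapping candidate spans are merged keeping the lowest score, ties to
  the leftmost start; coordinates are 1-based inclusive on the transcript
  sense strand.

Scanning uses a vectorized semi-global pass along each transcript that
lower-bounds the best window score at every end position; exact window
alignments (all lengths within miRNA length ± 2) are recomputed only where
the bound is within the cutoff. This is equivalent to scoring every window
at every offset, and is validated against exhaustive alignment enumeration
in the tests. Retention cutoff: score ≤ 4. No flanking-context,
conservation or free-energy terms are used. T and U are interchangeable on
input.

## GO enrichment

One-sided over-representation only: p = P(X ≥ k) for hypergeometric X,
computed via `scipy.stats.hypergeom.sf` (log-space internally), identical
to one-sided Fisher (asserted on random tables). BH adjustment via
`statsmodels` step-up with monotonicity. Terms with fewer than
`min_term_size` = 2 annotated genes, or zero overlap, are not tested;
annotation is flat term→gene with no GO-graph propagation to ancestors,
and FDR is computed globally across tested terms (per-namespace correction
is not performed by default).

## Synthetic data: what it emulates

`simulate_counts` draws baseline expression from a log-normal (median 20
CPM, log-sd 1.2 — a heavy-tailed bulk) and library counts from a
negative-binomial (gamma–Poisson) with dispersion 0.05 around condition
means; `dispersion = 0` switches to rounded expected counts (noise-free),
which is the regime where the exact-recovery properties hold. Planted
classes impose the four-condition sign structure directly: DE in CA/NC
(carried into CS/NC, matching the observed CA/CS concordance), reversal or
continuation in CCA/CA, and CS- or CCA-specific response. Default
fractions (4% DE-only, 6% reversed, 0.2% continued, 3% CS-specific, 2%
CCA-specific of 10,000 genes) give ~10% of genes DE under acclimation with
~59% of those reversing — the same regime as the real study. Library depth
defaults to 2×10⁶ mapped reads per condition.

Planted effects are placed away from the detection boundary: down-movers
start at or above a CPM floor (default 100) and up-movers at floor/fold,
rising into the upper quartile as the down-movers leave it. The placement
keeps the per-library upper-quartile factors comparable (an unbalanced
placement measurably biases normalized ratios) and puts planted genes in
the regime the rules are designed for, which is what makes ≥ 95% recall a
meaningful specification of the generator rather than an accident of
seeds. Marginal detection near the thresholds is exercised separately by
the noise-free tests at a floor of 50 CPM, where recovery is exact.

`simulate_sequences` plants target sites constructively: starting from a
perfect reverse complement it introduces seed mismatches (+2), non-seed
mismatches (+1; the target base is set equal to the miRNA base, which can
neither pair nor wobble) and non-seed G:U wobbles (+0.5) until the
requested score is reached, then re-scores the window with the production
aligner and rejects any placement that does not reproduce the request
exactly. Sites are spaced so merging cannot collapse two plants. One
above-cutoff site (score 4.5) is planted as a negative control.
`simulate_reads` composes 17–28 nt transcript fragments with 0–21 nt of 3'
adaptor carry-over and verifies each read against the trimming rule at
generation time, so the recorded truth is rule-consistent by construction.
`simulate_annotation` plants one term drawing half its 100 genes from the
designated (reversed) set. `simulate_study` wires the layers together:
reversed miRNAs are paired with oppositely reversed mRNAs, and those mRNAs
(plus decoys) receive transcript sequences with planted sites, giving
known anti-correlated pairs.

What passing the synthetic suite does **not** show: robustness to
replicate-free biological variability beyond NB dispersion 0.05, to
compositional library effects stronger than the planted ones, to
sequencing error in counts, or to the annotation and transcript-model
uncertainty of a real genome. The generator validates the machinery, not
the biology.

## Problem sizes and determinism

Default validation sizes — 10,000 genes, 120 miRNAs, 60 transcripts of
500 nt, 50 GO terms, 500 reads — are chosen so the entire suite and the
acceptance script each complete in well under a minute of compute while
leaving planted-statistic standard errors small relative to their margins.
All generators are pure functions of (config, seed); every CLI entry point
that draws randomness requires an explicit `--seed`. Output TSVs have
fixed column order, sorted rows and fixed float formats (scores one
decimal, p-values six significant digits), so reruns are byte-identical.

## Known limitations

* Novel-miRNA discovery, degradome/5'RACE analysis, secondary structure,
  conservation filtering and GO-graph handling are out of scope.
* The low-quality read rule and the indel conventions in target scoring
  are this package's documented choices; other implementations of the
  same penalty table may differ on bulged sites.
* The maximum of 2 indels per site bounds the window enumeration; sites
  requiring more gaps are not found.
* Fold changes are undefined (reported as NaN) when a normalized count is
  zero on either side; DE status is still defined via the on/off rule.
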