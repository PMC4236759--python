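# chillseq

Rule-based analysis of multi-condition chilling-stress expression profiling
in plants, built around the four-condition design used for cassava
(*Manihot esculenta*): a normal control (NC, 24°C), chilling acclimation
(CA, 14°C), chilling after acclimation (CCA, 14°C→4°C) and chilling shock
(CS, 24°C→4°C), each profiled as one pooled mRNA and one pooled small-RNA
library. The package is aimed at analysts who have per-condition count
tables (and optionally miRNA/transcript sequences and GO annotations) and
want the complete integrated analysis: expressed-gene calling, rule-based
differential expression, cross-condition overlap and expression-reversal
statistics, miRNA target prediction, miRNA–mRNA anti-correlation, and GO
term enrichment — plus a synthetic-data generator with planted ground truth
for validating every stage.

## The rules and models at the core

**Expressed/DE calling** (no replicates, so explicit rules instead of a
dispersion model). With CPM(g, ℓ) = raw(g, ℓ)/N(ℓ) × 10⁶ for library ℓ with
N(ℓ) mapped reads:

* gene g is *expressed* in ℓ iff CPM(g, ℓ) ≥ 10; below that the signal is
  treated as noise (effective expression 0);
* raw counts are made comparable by upper-quartile normalization: each
  library is divided by the 75th percentile of its nonzero counts (then
  rescaled by the geometric mean of the factors to stay count-like);
* g is *differentially expressed* between conditions A and B iff
  (1) it is expressed in both and max(nA, nB)/min(nA, nB) ≥ 4 on normalized
  counts, or (2) CPM < 10 in one condition and CPM > 40 in the other.

**Reversal analysis.** For the successive comparisons CA/NC then CCA/CA, a
DE gene whose direction flips (up→down or down→up) has *reversed*; one that
keeps its direction has *continued*. The headline statistic is the fraction
of CA/NC DE genes that reverse under subsequent chilling.

**miRNA target scoring.** A site is the minimum-penalty antiparallel
alignment of the miRNA against a transcript window: Watson–Crick pair 0,
G:U wobble 0.5, mismatch or indel 1, all doubled at miRNA seed positions
2–7; sites with total score ≤ 4 are putative targets. A DE miRNA and a DE
predicted target moving in opposite directions form an *anti-correlated
pair*.

**GO enrichment.** For a selection of m genes from a universe of M, a term
annotated to n genes with overlap k scores p = P(X ≥ k), X hypergeometric
(one-sided Fisher), with Benjamini–Hochberg FDR across terms.

## Worked example

The overlap/reversal layer can be exercised directly on the reference set
sizes of the cassava chilling study (reconstructed as gene sets; only
cardinalities matter):

```python
>>> from chillseq.worked_example import mrna_overlap_desets, mrna_trajectory_desets
>>> from chillseq import overlap_partition, reversal_summary, classify_trajectory
>>> ov = overlap_partition(*mrna_overlap_desets())
>>> ov.common, ov.pct_common_of_a, ov.pct_common_of_b
(2175, 76.2, 66.0)
>>> rev = reversal_summary(classify_trajectory(*mrna_trajectory_desets()))
>>> rev.pct_reversed("up"), rev.pct_reversed("down"), rev.total_reversed
(77.0, 47.6, 1801)
```

That is: of the 2,855 genes DE under chilling acclimation (CA vs NC) and
3,297 under chilling shock (CS vs NC), 2,175 are common (76.2% and 66.0% of
each set) — mild and severe chilling perturb the transcriptome similarly.
But after acclimation, further chilling *reverses* most of the acclimation
response: 77.0% of the 1,507 up-regulated genes and 47.6% of the 1,348
down-regulated genes flip direction from CA/NC to CCA/CA, 1,801 genes in
all.

A full synthetic study runs end to end from the command line:

```sh
chillseq simulate study --seed 7 --outdir sim/
chillseq run-all --counts sim/counts.tsv --totals sim/totals.tsv \
    --mirna-counts sim/mirna_counts.tsv --mirna-totals sim/mirna_totals.tsv \
    --mirna-fasta sim/mirnas.fa --transcript-fasta sim/transcripts.fa \
    --annotation sim/annotation.tsv --universe sim/universe.txt \
    --outdir results/
```

which writes per-stage TSVs (DE calls, overlap and reversal summaries,
target sites, anti-correlated pairs, enrichment) and a `manifest.json`.
Individual stages are also available (`chillseq trim | count | expression |
de | compare | trajectory | targets | anticorr | enrich`).

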