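"""File formats: FASTA/FASTQ via Biopython, TSV tables via pandas.

All writers emit deterministic, byte-stable output: fixed column order,
documented sort keys, fixed float precision (alignment scores one decimal,
p-values scientific with six significant digits).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import CountTable
from .go_enrichment import EnrichmentRecord
from .mirna_targeting import AntiCorrelatedPair, TargetSite
from .read_processing import Read

__all__ = [
    "read_fasta", "write_fasta", "read_fastq", "write_fastq",
    "read_count_table", "write_count_table",
    "write_de_table", "read_de_table",
    "write_sites", "read_sites", "write_pairs",
    "write_enrichment", "read_annotation_pairs",
]


class ParseError(ValueError):
    """Malformed input file."""


def read_fasta(path: str | Path, rna_as_dna: bool = True) -> dict[str, str]:
    """FASTA records as an ordered id -> uppercase sequence mapping.

    Wrapped and unwrapped files are equivalent; duplicate ids are an
    error. With ``rna_as_dna`` U is rewritten as T.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"{path}: duplicate id {rec.id!r}")
        seq = str(rec.seq).upper()
        if rna_as_dna:
            seq = seq.replace("U", "T")
        records[rec.id] = seq
    return records


def write_fasta(path: str | Path, records: Mapping[str, str],
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[Read]:
    """Four-line FASTQ (Phred+33) as a list of Reads; ids must be unique."""
    reads: list[Read] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(Read(rec.id, str(rec.seq).upper(), qual))
    return reads


def write_fastq(path: str | Path, reads: Iterable[Read]) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        qual = r.quality if r.quality is not None else "I" * len(r.sequence)
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_count_table(path: str | Path, totals_path: str | Path) -> CountTable:
    """Counts TSV (header ``gene_id<TAB>lib...``) plus a two-column totals
    TSV (``library<TAB>mapped_reads``)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.has_duplicates:
        raise ParseError(f"{path}: duplicate gene ids")
    try:
        counts = counts.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric counts ({exc})") from exc
    if (counts.values < 0).any():
        raise ParseError(f"{path}: negative counts")
    totals_df = pd.read_csv(totals_path, sep="\t", index_col=0)
    totals = totals_df.iloc[:, 0].astype(float)
    missing = [c for c in counts.columns if c not in totals.index]
    if missing:
        raise ParseError(f"{totals_path}: missing totals for {missing}")
    return CountTable(counts=counts, totals=totals)


def write_count_table(path: str | Path, totals_path: str | Path,
                      table: CountTable) -> None:
    counts = table.counts.sort_index()
    counts.index.name = "gene_id"
    counts.to_csv(path, sep="\t", float_format="%.4g")
    totals = table.totals.rename("mapped_reads")
    totals.index.name = "library"
    totals.to_csv(totals_path, sep="\t", float_format="%.10g")


def write_de_table(path: str | Path, calls: pd.DataFrame, comparison: str) -> None:
    """DE calls TSV: gene_id, comparison, status, fold_change, criterion;
    rows sorted by gene id."""
    out = calls.sort_index().copy()
    out.insert(0, "comparison", comparison)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.4f")


def read_de_table(path: str | Path) -> tuple[pd.DataFrame, str]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    comparisons = df["comparison"].unique()
    if len(comparisons) != 1:
        raise ParseError(f"{path}: expected a single comparison, got "
                         f"{list(comparisons)}")
    return df.drop(columns=["comparison"]), str(comparisons[0])


_SITE_COLUMNS = ["mirna_id", "transcript_id", "start", "end", "score",
                 "alignment_mirna", "alignment_symbols", "alignment_target"]


def write_sites(path: str | Path, sites: Iterable[TargetSite]) -> None:
    """Target sites TSV; coordinates 1-based inclusive on the transcript
    sense strand; scores one decimal."""
    rows = [(s.mirna_id, s.transcript_id, s.start, s.end, f"{s.score:.1f}",
             s.aln_mirna, s.aln_symbols, s.aln_target) for s in sites]
    pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> list[TargetSite]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        TargetSite(r.mirna_id, r.transcript_id, int(r.start), int(r.end),
                   float(r.score), r.alignment_mirna, r.alignment_symbols,
                   r.alignment_target)
        for r in df.itertuples()
    ]


def write_pairs(path: str | Path, pairs: Iterable[AntiCorrelatedPair]) -> None:
    rows = [(p.mirna_id, p.transcript_id, p.comparison, p.mirna_status,
             p.target_status) for p in pairs]
    pd.DataFrame(rows, columns=["mirna_id", "transcript_id", "comparison",
                                "mirna_status", "target_status"]
                 ).to_csv(path, sep="\t", index=False)


def write_enrichment(path: str | Path,
                     records: Iterable[EnrichmentRecord]) -> None:
    rows = [(r.term, r.k, r.m, r.n, r.M, f"{r.p:.5e}", f"{r.fdr:.5e}")
            for r in records]
    pd.DataFrame(rows, columns=["term", "k", "m", "n", "M", "p", "fdr"]
                 ).to_csv(path, sep="\t", index=False)


def read_annotation_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV ``gene_id<TAB>term_id``, one pair per line."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            pairs.append((parts[0], parts[1]))
    return pairs
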