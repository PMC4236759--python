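"""End-to-end orchestration: expression -> DE -> comparison/trajectory ->
targets -> anti-correlation -> enrichment, with a machine-readable
manifest.

Outputs are deterministic: every TSV has a fixed column order and sorted
rows, so a rerun on identical inputs and configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .condition_comparison import (DESet, classify_trajectory, deset_from_table,
                                   overlap_partition, reversal_summary)
from .expression import DEConfig, build_profile, call_de_table
from .go_enrichment import enrich
from .io import (read_annotation_pairs, read_count_table, read_fasta,
                 write_de_table, write_enrichment, write_pairs, write_sites)
from .go_enrichment import Annotation
from .mirna_targeting import (TargetScoringConfig, find_anticorrelated_pairs,
                              predict_targets)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

DEFAULT_COMPARISONS = (("CA", "NC"), ("CCA", "CA"), ("CS", "NC"),
                       ("CCA", "NC"), ("CS", "CA"), ("CS", "CCA"))


@dataclass
class RunConfig:
    """Paths and parameters of a full analysis run.

    The mRNA count table is the primary entry point; miRNA counts,
    sequence FASTAs and the annotation are optional and switch their
    stages on. Comparisons are ordered (first, second) condition pairs;
    ``trajectory`` names the successive pair of comparisons whose reversal
    structure is analyzed; ``overlap`` the pair whose DE sets are
    partitioned.
    """

    counts: str
    totals: str
    outdir: str
    mirna_counts: str | None = None
    mirna_totals: str | None = None
    mirna_fasta: str | None = None
    transcript_fasta: str | None = None
    annotation: str | None = None
    universe: str | None = None
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    trajectory: tuple[tuple[str, str], tuple[str, str]] = (("CA", "NC"), ("CCA", "CA"))
    overlap: tuple = ((("CA", "NC"), ("CS", "NC")),
                      (("CCA", "NC"), ("CS", "NC")))
    de: DEConfig = field(default_factory=DEConfig)
    scoring: TargetScoringConfig = field(default_factory=TargetScoringConfig)
    min_term_size: int = 2

    def to_jsonable(self) -> dict:
        return {
            "counts": self.counts, "totals": self.totals,
            "outdir": self.outdir,
            "mirna_counts": self.mirna_counts,
            "mirna_totals": self.mirna_totals,
            "mirna_fasta": self.mirna_fasta,
            "transcript_fasta": self.transcript_fasta,
            "annotation": self.annotation, "universe": self.universe,
            "comparisons": [list(c) for c in self.comparisons],
            "trajectory": [list(c) for c in self.trajectory],
            "overlap": [[list(x) for x in pair] for pair in self.overlap],
            "de": vars(self.de).copy(),
            "scoring": vars(self.scoring).copy(),
            "min_term_size": self.min_term_size,
        }


def _label(pair: tuple[str, str]) -> str:
    return f"{pair[0]}/{pair[1]}"


def _fname(pair: tuple[str, str]) -> str:
    return f"{pair[0]}_{pair[1]}"


def run_all(cfg: RunConfig) -> dict:
    """Execute every configured stage; returns the in-memory results and
    writes one TSV per stage plus ``manifest.json`` under ``outdir``."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    results: dict = {}

    # 1. expression
    table = read_count_table(cfg.counts, cfg.totals)
    profile = build_profile(table, cfg.de)
    prof_df = pd.concat(
        {"cpm": profile.cpm, "normalized": profile.normalized}, axis=1)
    prof_df.columns = [f"{a}_{b}" for a, b in prof_df.columns]
    prof_df.sort_index().rename_axis("gene_id").to_csv(
        out / "profile.tsv", sep="\t", float_format="%.4f")
    stages.append("expression")
    results["profile"] = profile

    # 2. differential expression per comparison
    desets: dict[str, DESet] = {}
    for pair in cfg.comparisons:
        label = _label(pair)
        calls = call_de_table(profile, pair, cfg.de)
        write_de_table(out / f"de_{_fname(pair)}.tsv", calls, label)
        desets[label] = deset_from_table(calls, label)
    stages.append("de")
    results["desets"] = desets

    # 3. overlap partitions
    overlaps = {}
    for pair_a, pair_b in cfg.overlap:
        la, lb = _label(pair_a), _label(pair_b)
        if la in desets and lb in desets:
            summ = overlap_partition(desets[la], desets[lb])
            summ.to_frame().to_csv(
                out / f"overlap_{_fname(pair_a)}_vs_{_fname(pair_b)}.tsv",
                sep="\t", index=False, float_format="%.2f")
            overlaps[(la, lb)] = summ
    stages.append("compare")
    results["overlaps"] = overlaps

    # 4. trajectory / reversal
    t1, t2 = (_label(p) for p in cfg.trajectory)
    calls = classify_trajectory(desets[t1], desets[t2])
    pd.DataFrame(
        [(c.gene, c.first_status, c.second_status, c.klass) for c in calls],
        columns=["gene_id", "first_status", "second_status", "class"],
    ).to_csv(out / "trajectory.tsv", sep="\t", index=False)
    rev = reversal_summary(calls)
    rev.to_frame().to_csv(out / "reversal_summary.tsv", sep="\t",
                          index=False, float_format="%.1f")
    reversed_genes = sorted(c.gene for c in calls if c.klass == "reversed")
    stages.append("trajectory")
    results["trajectory"] = calls
    results["reversal"] = rev
    results["reversed_genes"] = reversed_genes

    # 5. miRNA side
    mirna_desets: dict[str, DESet] = {}
    if cfg.mirna_counts:
        if not cfg.mirna_totals:
            raise ValueError("mirna_counts given without mirna_totals")
        mtable = read_count_table(cfg.mirna_counts, cfg.mirna_totals)
        mprofile = build_profile(mtable, cfg.de)
        for pair in cfg.comparisons:
            label = _label(pair)
            mcalls = call_de_table(mprofile, pair, cfg.de)
            write_de_table(out / f"de_mirna_{_fname(pair)}.tsv", mcalls, label)
            mirna_desets[label] = deset_from_table(mcalls, label)
        stages.append("mirna_de")
        results["mirna_desets"] = mirna_desets

    # 6. target prediction
    sites = None
    if cfg.mirna_fasta and cfg.transcript_fasta:
        mirnas = read_fasta(cfg.mirna_fasta)
        transcripts = read_fasta(cfg.transcript_fasta)
        sites = predict_targets(mirnas, transcripts, cfg.scoring)
        write_sites(out / "sites.tsv", sites)
        stages.append("targets")
        results["sites"] = sites

    # 7. anti-correlated pairs
    if sites is not None and mirna_desets:
        for label, mset in mirna_desets.items():
            if label not in desets:
                continue
            pairs = find_anticorrelated_pairs(mset, desets[label], sites)
            write_pairs(out / f"anticorr_{label.replace('/', '_')}.tsv", pairs)
            results.setdefault("anticorr", {})[label] = pairs
        stages.append("anticorr")

    # 8. enrichment of the reversed genes
    if cfg.annotation:
        ann_pairs = read_annotation_pairs(cfg.annotation)
        if cfg.universe:
            with open(cfg.universe) as fh:
                universe = [line.strip() for line in fh if line.strip()]
        else:
            universe = list(table.genes)
        annotation = Annotation.from_pairs(ann_pairs, universe)
        if not reversed_genes:
            raise ValueError("enrichment requested but no reversed genes found")
        records = enrich(reversed_genes, annotation, cfg.min_term_size)
        write_enrichment(out / "enrichment.tsv", records)
        stages.append("enrich")
        results["enrichment"] = records

    config_json = json.dumps(cfg.to_jsonable(), sort_keys=True)
    manifest = {
        "tool": "chillseq",
        "version": __version__,
        "stages": stages,
        "config": cfg.to_jsonable(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "inputs": {k: v for k, v in cfg.to_jsonable().items()
                   if k.endswith(("counts", "totals", "fasta", "annotation",
                                  "universe")) and v},
        "outputs": sorted(p.name for p in out.iterdir() if p.suffix == ".tsv"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results
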