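"""Genomic peak categorization against a gene annotation.

Peaks (BED intervals) are assigned to one of seven feature categories —
promoter, 5'UTR, 3'UTR, exon, intron, downstream, intergenic — by their
midpoint, with a fixed priority order resolving overlaps, and summarised as
a percentage distribution (the numbers behind the usual annotation pie
charts).

Coordinate conventions: BED is 0-based half-open, GTF 1-based closed; both
conversions live in the readers, and everything downstream is 0-based
half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "PRIORITY",
    "GenomicFeatureIndex",
    "PeakSet",
    "build_feature_index",
    "read_bed",
    "annotate_peaks",
    "plot_distribution",
]

#: category priority, highest first; a midpoint in several features gets the
#: first matching category.
PRIORITY = ("promoter", "five_prime_utr", "three_prime_utr", "exon", "intron", "downstream", "intergenic")

_UTR5_NAMES = {"five_prime_utr", "5utr", "5'utr", "five_prime_UTR"}
_UTR3_NAMES = {"three_prime_utr", "3utr", "3'utr", "three_prime_UTR"}


@dataclass
class PeakSet:
    intervals: list  # (chrom, start, end), 0-based half-open
    names: list = field(default_factory=list)
    scores: list = field(default_factory=list)

    def __post_init__(self):
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        if not self.names:
            self.names = [f"peak{i + 1:05d}" for i in range(len(self.intervals))]


@dataclass
class GenomicFeatureIndex:
    """Interval trees per category per chromosome, queryable by point."""

    trees: dict  # category -> chrom -> IntervalTree
    promoter_up: int
    promoter_down: int
    downstream: int
    n_genes: int
    n_skipped: int = 0

    def category_at(self, chrom: str, pos: int) -> str | None:
        """Highest-priority category covering a point, or None if the
        chromosome is absent from the annotation entirely."""
        known = any(chrom in by_chrom for by_chrom in self.trees.values())
        if not known:
            return None
        for cat in PRIORITY[:-1]:
            tree = self.trees.get(cat, {}).get(chrom)
            if tree is not None and tree.overlaps_point(pos):
                return cat
        return "intergenic"


def build_feature_index(
    gtf_path,
    promoter_up: int = 2000,
    promoter_down: int = 500,
    downstream: int = 3000,
) -> GenomicFeatureIndex:
    """Build the category index from a GTF with gene/exon/UTR records.

    The promoter is the strand-aware window [TSS − promoter_up, TSS +
    promoter_down) (mirrored on the minus strand); ``downstream`` extends
    past the gene end.  Gene bodies provide the intron fallback (gene minus
    exon).  GTF features other than gene/exon/UTR are ignored; malformed
    lines are skipped and counted.
    """
    gtf_path = Path(gtf_path)
    n_skipped = 0
    clean_lines = []
    with open(gtf_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                n_skipped += 1
                continue
            clean_lines.append(line)
    if n_skipped:
        warnings.warn(f"{n_skipped} malformed GTF line(s) skipped")
    db = gffutils.create_db(
        "".join(clean_lines),
        dbfn=":memory:",
        from_string=True,
        force=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    trees: dict = {cat: {} for cat in ("promoter", "five_prime_utr", "three_prime_utr", "exon", "gene", "downstream")}

    def add(cat, chrom, start0, end0):
        if end0 <= start0:
            return
        trees[cat].setdefault(chrom, IntervalTree()).addi(start0, end0)

    n_genes = 0
    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        start0, end0 = feat.start - 1, feat.end  # GTF 1-based closed -> half-open
        if ftype == "gene":
            n_genes += 1
            add("gene", feat.seqid, start0, end0)
            if feat.strand == "-":
                tss = end0 - 1
                add("promoter", feat.seqid, tss - promoter_down + 1, tss + promoter_up + 1)
                add("downstream", feat.seqid, start0 - downstream, start0)
            else:
                tss = start0
                add("promoter", feat.seqid, tss - promoter_up, tss + promoter_down)
                add("downstream", feat.seqid, end0, end0 + downstream)
        elif ftype == "exon":
            add("exon", feat.seqid, start0, end0)
        elif ftype in _UTR5_NAMES:
            add("five_prime_utr", feat.seqid, start0, end0)
        elif ftype in _UTR3_NAMES:
            add("three_prime_utr", feat.seqid, start0, end0)

    # the intron fallback is "inside a gene but in no exon": store gene spans
    # under the intron slot and let priority order do the subtraction.
    trees["intron"] = trees.pop("gene")
    return GenomicFeatureIndex(
        trees=trees,
        promoter_up=promoter_up,
        promoter_down=promoter_down,
        downstream=downstream,
        n_genes=n_genes,
        n_skipped=n_skipped,
    )


def read_bed(path) -> PeakSet:
    """Read a BED3+ peak file (0-based half-open, as BED is defined)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return PeakSet(intervals=[])
    if df.empty:
        return PeakSet(intervals=[])
    intervals = list(zip(df[0].astype(str), df[1].astype(int), df[2].astype(int)))
    names = df[3].astype(str).tolist() if df.shape[1] > 3 else []
    scores = df[4].tolist() if df.shape[1] > 4 else []
    return PeakSet(intervals=intervals, names=names, scores=scores)


def annotate_peaks(peaks: PeakSet, index: GenomicFeatureIndex):
    """Assign each peak one category by its midpoint and summarise.

    Returns (per-peak DataFrame, distribution dict of percentages summing to
    100 when any peaks exist).  Peaks on chromosomes absent from the
    annotation fall back to intergenic with a warning.
    """
    records = []
    unknown_chroms = set()
    for name, (chrom, start, end) in zip(peaks.names, peaks.intervals):
        mid = (start + end) // 2
        cat = index.category_at(chrom, mid)
        if cat is None:
            unknown_chroms.add(chrom)
            cat = "intergenic"
        records.append({"peak": name, "chrom": chrom, "start": start, "end": end, "midpoint": mid, "category": cat})
    if unknown_chroms:
        warnings.warn(f"peaks on chromosome(s) absent from annotation: {sorted(unknown_chroms)}; assigned intergenic")
    df = pd.DataFrame(records, columns=["peak", "chrom", "start", "end", "midpoint", "category"])
    if df.empty:
        return df, {}
    counts = df["category"].value_counts()
    dist = {cat: 100.0 * counts.get(cat, 0) / len(df) for cat in PRIORITY}
    return df, dist


def plot_distribution(dist: dict, path=None, title: str = "Peak category distribution"):
    """Simple pie chart of the category distribution; returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = [c for c in PRIORITY if dist.get(c, 0) > 0]
    fig, ax = plt.subplots()
    ax.pie([dist[c] for c in cats], labels=cats, autopct="%1.1f%%")
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
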