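"""Region classification, TSS-relative depth profiles, and detection tables.

Exome capture pulls down fragments that flank the probe-targeted exons, so a
few percent of aligned read bases land in promoters.  This module quantifies
that off-target fraction: every covered base is attributed to exactly one
region class (promoter > exon > intron > intergenic), promoter depth is
re-expressed in TSS-relative coordinates, and per-50-bp detection rates say
how far upstream of the TSS the data still see each gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome import GeneModel, PromoterWindow, to_relative

REGIONS = ("promoter", "exon", "intron", "intergenic")

__all__ = [
    "PileupColumn",
    "RegionTally",
    "classify_regions",
    "relative_depth_profile",
    "detection_table",
    "average_over_samples",
    "read_pileup",
    "write_pileup",
    "pileup_from_bam",
]


@dataclass(frozen=True)
class PileupColumn:
    """Per-position aligned depth and base composition."""

    chrom: str
    pos: int  # 1-based
    depth: int
    base_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if sum(self.base_counts.values()) > self.depth:
            raise ValueError("base counts exceed depth")


@dataclass
class RegionTally:
    """Depth-weighted covered-base counts per region class."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = {r: int(self.counts.get(r, 0)) for r in REGIONS}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percentages(self, ndigits: int = 2) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            return {r: 0.0 for r in REGIONS}
        return {r: round(100.0 * c / tot, ndigits) for r, c in self.counts.items()}


def _window_trees(windows: Sequence[PromoterWindow]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        if w.primary:
            trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end + 1, w)
    return trees


def _gene_trees(
    genes: Sequence[GeneModel],
) -> tuple[dict[str, IntervalTree], dict[str, IntervalTree]]:
    """Interval trees of exons and of gene spans (for intron calls)."""
    exons: dict[str, IntervalTree] = {}
    spans: dict[str, IntervalTree] = {}
    for g in genes:
        if not g.exons:
            continue
        for s, e in g.exons:
            exons.setdefault(g.chrom, IntervalTree()).addi(s, e + 1)
        lo = min(s for s, _ in g.exons)
        hi = max(e for _, e in g.exons)
        spans.setdefault(g.chrom, IntervalTree()).addi(lo, hi + 1)
    return exons, spans


def classify_regions(
    pileup: Iterable[PileupColumn],
    windows: Sequence[PromoterWindow],
    genes: Sequence[GeneModel] = (),
) -> RegionTally:
    """Attribute depth-weighted covered bases to one region class each.

    Precedence is promoter > exon > intron > intergenic, so a base inside a
    promoter window that also overlaps an annotated first exon counts as
    promoter.  Positions on chromosomes absent from the annotation are
    counted intergenic with a warning.
    """
    wtrees = _window_trees(windows)
    etrees, strees = _gene_trees(genes)
    known = set(wtrees) | {g.chrom for g in genes}
    warned: set[str] = set()
    counts = dict.fromkeys(REGIONS, 0)
    for col in pileup:
        if col.depth <= 0:
            continue
        if col.chrom not in known:
            if col.chrom not in warned:
                warned.add(col.chrom)
                warnings.warn(
                    f"chromosome {col.chrom!r} absent from annotation; "
                    "counting as intergenic"
                )
            counts["intergenic"] += col.depth
            continue
        if col.chrom in wtrees and wtrees[col.chrom].overlaps(col.pos):
            counts["promoter"] += col.depth
        elif col.chrom in etrees and etrees[col.chrom].overlaps(col.pos):
            counts["exon"] += col.depth
        elif col.chrom in strees and strees[col.chrom].overlaps(col.pos):
            counts["intron"] += col.depth
        else:
            counts["intergenic"] += col.depth
    return RegionTally(counts)


def relative_depth_profile(
    pileup: Iterable[PileupColumn],
    windows: Sequence[PromoterWindow],
) -> pd.Series:
    """Sum depth at each TSS-relative position across all promoter windows.

    Minus-strand windows contribute at reflected positions, so two genes
    with the same TSS-relative coverage shape contribute identically.
    Returns a Series indexed by relative position (no 0), covering
    rel_lo..rel_hi, zero-filled.
    """
    if not windows:
        raise ValueError("no windows supplied")
    lo = min(w.rel_lo for w in windows)
    hi = max(w.rel_hi for w in windows)
    index = [r for r in range(lo, hi + 1) if r != 0]
    profile = dict.fromkeys(index, 0)
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end + 1, w)
    for col in pileup:
        if col.depth <= 0 or col.chrom not in trees:
            continue
        for iv in trees[col.chrom].at(col.pos):
            w: PromoterWindow = iv.data
            profile[to_relative(w, col.pos)] += col.depth
    return pd.Series(profile, name="depth").sort_index()


def _bins(rel_lo: int, rel_hi: int, width: int = 50) -> list[tuple[str, int, int]]:
    """50-bp bins from downstream end toward upstream: (+100..+51), ... (-451..-500)."""
    bins: list[tuple[str, int, int]] = []
    r = rel_hi
    while r >= 1:
        lo = max(1, r - width + 1)
        bins.append((f"{r} to {lo}", lo, r))
        r = lo - 1
    r = -1
    while r >= rel_lo:
        lo = max(rel_lo, r - width + 1)
        bins.append((f"{r} to {lo}", lo, r))
        r = lo - 1
    return bins


def detection_table(
    pileup: Iterable[PileupColumn],
    windows: Sequence[PromoterWindow],
    min_depth: int = 1,
    bin_width: int = 50,
) -> pd.DataFrame:
    """Per-50-bp-bin promoter detection counts and rates.

    A gene is detected in a bin iff at least one position of that bin has
    depth >= *min_depth*.  Rates are percentages of all genes, to 1 dp.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not windows:
        raise ValueError("no windows supplied")
    rel_lo = min(w.rel_lo for w in windows)
    rel_hi = max(w.rel_hi for w in windows)
    bins = _bins(rel_lo, rel_hi, bin_width)
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end + 1, w)
    detected: dict[str, set[str]] = {label: set() for label, _, _ in bins}
    bin_of: dict[int, str] = {}
    for label, blo, bhi in bins:
        for r in range(blo, bhi + 1):
            if r != 0:
                bin_of[r] = label
    for col in pileup:
        if col.depth < min_depth or col.chrom not in trees:
            continue
        for iv in trees[col.chrom].at(col.pos):
            w: PromoterWindow = iv.data
            detected[bin_of[to_relative(w, col.pos)]].add(w.gene_id)
    total = len(windows)
    rows = [
        {
            "bin": label,
            "rel_lo": blo,
            "rel_hi": bhi,
            "detected": len(detected[label]),
            "total": total,
            "rate": round(100.0 * len(detected[label]) / total, 1) if total else 0.0,
        }
        for label, blo, bhi in bins
    ]
    return pd.DataFrame(rows)


def average_over_samples(tables, ndigits: int | None = None):
    """Average percentages across per-sample tables of identical structure.

    Accepts a list of :class:`RegionTally` (returns a Series of mean
    percentages per region, 2 dp default), a list of percentage mappings or
    Series of identical keys (mean per key, 2 dp default), or a list of
    detection-table DataFrames (returns the first table's bins with a mean
    ``rate`` column, 1 dp default).
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one table")
    if isinstance(tables[0], RegionTally):
        nd = 2 if ndigits is None else ndigits
        pct = pd.DataFrame([t.percentages(ndigits=10) for t in tables])
        return pct.mean().round(nd)
    if isinstance(tables[0], (dict, pd.Series)):
        nd = 2 if ndigits is None else ndigits
        df = pd.DataFrame([dict(t) for t in tables])
        if df.isna().any().any():
            raise ValueError("percentage tables have mismatched keys")
        return df.mean().round(nd)
    nd = 1 if ndigits is None else ndigits
    ref = tables[0]
    for t in tables[1:]:
        if list(t["bin"]) != list(ref["bin"]):
            raise ValueError("detection tables have mismatched bins")
    out = ref[["bin", "rel_lo", "rel_hi"]].copy()
    out["rate"] = (
        pd.concat([t["rate"] for t in tables], axis=1).mean(axis=1).round(nd)
    )
    return out


# ---------------------------------------------------------------------------
# pileup IO

PILEUP_COLUMNS = ["chrom", "pos", "depth", "A", "C", "G", "T", "del"]


def read_pileup(path: str) -> Iterator[PileupColumn]:
    """Stream pileup columns from the canonical TSV format.

    Columns: chrom, pos (1-based), depth, A, C, G, T, del counts.  A header
    line is permitted and detected.
    """
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "chrom":
                continue
            chrom, pos, depth = parts[0], int(parts[1]), int(parts[2])
            bases = {}
            if len(parts) >= 8:
                bases = {
                    b: int(parts[i])
                    for i, b in zip(range(3, 8), ("A", "C", "G", "T", "del"))
                }
            yield PileupColumn(chrom, pos, depth, bases)


def write_pileup(columns: Iterable[PileupColumn], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PILEUP_COLUMNS) + "\n")
        for c in columns:
            bc = c.base_counts
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.depth}\t"
                f"{bc.get('A', 0)}\t{bc.get('C', 0)}\t{bc.get('G', 0)}\t"
                f"{bc.get('T', 0)}\t{bc.get('del', 0)}\n"
            )


def pileup_from_bam(path: str, fasta_path: str | None = None) -> Iterator[PileupColumn]:
    """Extract pileup columns from a coordinate-sorted BAM via pysam."""
    import pysam

    with pysam.AlignmentFile(path) as bam:
        for col in bam.pileup(fastafile=None, truncate=False):
            bases: dict[str, int] = {}
            for read in col.pileups:
                if read.is_del or read.is_refskip:
                    bases["del"] = bases.get("del", 0) + 1
                    continue
                b = read.alignment.query_sequence[read.query_position].upper()
                if b in "ACGT":
                    bases[b] = bases.get(b, 0) + 1
            yield PileupColumn(
                col.reference_name, col.reference_pos + 1, col.nsegments, bases
            )
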