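"""Stranded gene models, promoter windows, and TSS-relative coordinates.

The coordinate convention throughout the package is 1-based and closed, with
the transcription start site at relative position +1 and no relative
position 0: ``-1`` is the base immediately upstream of the TSS, so a window
from -500 to +100 spans exactly 600 bases.  On the minus strand "upstream"
means higher genomic coordinate, and windows are reflected accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

DEFAULT_WINDOW = (-500, 100)
DEFAULT_CORE = (-100, 100)

__all__ = [
    "GeneModel",
    "PromoterWindow",
    "build_windows",
    "to_relative",
    "to_genomic",
    "rel_shift",
    "rel_length",
    "read_bed",
    "read_gff3",
    "write_windows_bed",
    "promoter_sequence",
]


class CoordinateError(ValueError):
    """A genomic or TSS-relative position outside its legal range."""


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to the attributes promoter analysis needs.

    ``tss`` is the 1-based genomic position of the transcription start
    site; ``exons`` are optional 1-based closed intervals used for
    region-precedence classification.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 1:
            raise ValueError(f"tss must be >= 1, got {self.tss}")
        exons = sorted(tuple(map(int, e)) for e in self.exons)
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        object.__setattr__(self, "exons", tuple(exons))


@dataclass(frozen=True)
class PromoterWindow:
    """The genomic footprint of a TSS-relative window for one gene.

    ``start``/``end`` are 1-based closed genomic coordinates.  ``primary``
    is False when an earlier gene in annotation order already claimed an
    overlapping interval on the same chromosome; non-primary windows are
    kept for per-gene reporting but excluded from base attribution.
    ``truncated`` flags windows clipped at the start of the contig.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    rel_lo: int = DEFAULT_WINDOW[0]
    rel_hi: int = DEFAULT_WINDOW[1]
    core_lo: int = DEFAULT_CORE[0]
    core_hi: int = DEFAULT_CORE[1]
    primary: bool = True
    truncated: bool = False
    start: int = field(init=False)
    end: int = field(init=False)

    def __post_init__(self) -> None:
        if self.rel_lo >= 0 or self.rel_hi <= 0:
            raise ValueError("window bounds must satisfy rel_lo < 0 < rel_hi")
        if self.strand == "+":
            start = self.tss + self.rel_lo
            end = self.tss + self.rel_hi - 1
        elif self.strand == "-":
            start = self.tss - self.rel_hi + 1
            end = self.tss - self.rel_lo
        else:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        truncated = self.truncated
        if start < 1:
            start = 1
            truncated = True
        if end < 1:
            raise CoordinateError(
                f"window for {self.gene_id} lies entirely below position 1"
            )
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        object.__setattr__(self, "truncated", truncated)

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, gpos: int) -> bool:
        return self.start <= gpos <= self.end


def to_relative(window: PromoterWindow, gpos: int) -> int:
    """Map a genomic position inside *window* to its TSS-relative position.

    +1 is the TSS base; negative values are upstream.  Raises
    :class:`CoordinateError` if *gpos* is outside the window.
    """
    if not window.contains(gpos):
        raise CoordinateError(
            f"position {gpos} outside window [{window.start}, {window.end}] "
            f"of {window.gene_id}"
        )
    if window.strand == "+":
        off = gpos - window.tss
        return off + 1 if off >= 0 else off
    off = window.tss - gpos
    return off + 1 if off >= 0 else off


def to_genomic(window: PromoterWindow, rel: int) -> int:
    """Inverse of :func:`to_relative`; rejects relative position 0."""
    if rel == 0:
        raise CoordinateError("relative position 0 does not exist")
    if not (window.rel_lo <= rel <= window.rel_hi):
        raise CoordinateError(
            f"relative position {rel} outside bounds "
            f"[{window.rel_lo}, {window.rel_hi}]"
        )
    off = rel - 1 if rel > 0 else rel
    if window.strand == "+":
        return window.tss + off
    return window.tss - off


def rel_shift(rel: int, delta: int) -> int:
    """Move *delta* bases downstream in TSS-relative coordinates, skipping 0."""
    if rel == 0:
        raise CoordinateError("relative position 0 does not exist")
    off = rel - 1 if rel > 0 else rel
    out = off + delta
    return out + 1 if out >= 0 else out


def rel_length(rel_lo: int, rel_hi: int) -> int:
    """Number of bases between two relative positions inclusive (no zero)."""
    lo = rel_lo - 1 if rel_lo > 0 else rel_lo
    hi = rel_hi - 1 if rel_hi > 0 else rel_hi
    return hi - lo + 1


def build_windows(
    genes: Sequence[GeneModel],
    rel_lo: int = DEFAULT_WINDOW[0],
    rel_hi: int = DEFAULT_WINDOW[1],
    core_lo: int = DEFAULT_CORE[0],
    core_hi: int = DEFAULT_CORE[1],
) -> list[PromoterWindow]:
    """Derive one promoter window per gene.

    Where two windows overlap on the same chromosome, only the first gene
    in input order keeps ``primary=True`` (and hence claims the overlapping
    bases for attribution); both windows are returned.  Windows running off
    the start of the contig are truncated and flagged.
    """
    if not (rel_lo < 0 < rel_hi):
        raise ValueError("require rel_lo < 0 < rel_hi")
    claimed: dict[str, IntervalTree] = {}
    out: list[PromoterWindow] = []
    for g in genes:
        w = PromoterWindow(
            gene_id=g.gene_id, chrom=g.chrom, strand=g.strand, tss=g.tss,
            rel_lo=rel_lo, rel_hi=rel_hi, core_lo=core_lo, core_hi=core_hi,
        )
        tree = claimed.setdefault(g.chrom, IntervalTree())
        if tree.overlap(w.start, w.end + 1):
            w = replace(w, primary=False)
        else:
            tree.addi(w.start, w.end + 1)
        out.append(w)
    return out


# ---------------------------------------------------------------------------
# annotation IO

def read_bed(path: str) -> list[GeneModel]:
    """Read gene models from BED6.

    BED is half-open and 0-based; the TSS is the interval start for plus-
    strand genes and the interval end for minus-strand genes, converted to
    1-based on read.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            start_i, end_i = int(start), int(end)
            tss = start_i + 1 if strand == "+" else end_i
            genes.append(GeneModel(name, chrom, strand, tss))
    return genes


def read_gff3(path: str, feature: str = "gene") -> list[GeneModel]:
    """Read gene models from GFF3 (1-based closed already)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature:
                continue
            chrom, _src, _feat, start, end, _score, strand, _frame, attrs = parts[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("ID") or attr.get("gene_id") or attr.get("Name")
            if gid is None:
                raise ValueError(f"gene feature without ID in {path}")
            tss = int(start) if strand == "+" else int(end)
            genes.append(GeneModel(gid, chrom, strand, tss))
    return genes


def write_windows_bed(windows: Iterable[PromoterWindow], path: str) -> None:
    """Write windows as BED6 (0-based half-open) with gene_id as name."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(
                f"{w.chrom}\t{w.start - 1}\t{w.end}\t{w.gene_id}\t"
                f"{int(w.primary)}\t{w.strand}\n"
            )


def promoter_sequence(window: PromoterWindow, fasta) -> str:
    """Fetch the window sequence in the TSS-relative frame (5'->3').

    *fasta* is a :class:`pyfaidx.Fasta` (or any mapping of chrom to
    string-indexable sequence).  Minus-strand windows are reverse
    complemented so index 0 corresponds to ``rel_lo``.
    """
    seq = str(fasta[window.chrom][window.start - 1: window.end]).upper()
    if window.strand == "-":
        seq = _revcomp(seq)
    return seq


_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def warn_unknown_chrom(chrom: str) -> None:
    warnings.warn(f"chromosome {chrom!r} absent from annotation; counted intergenic",
                  stacklevel=3)
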