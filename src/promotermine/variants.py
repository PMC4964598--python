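"""Promoter-variant mining, a minimal pileup caller, and change spectra.

Variant calls are trusted only where enough promoter-mapped sequence
supports them: the mining filter keeps a record when its position falls in
a promoter window and the site depth reaches the minimum (default 4
sequences).  Retained variants are re-expressed in TSS-relative
coordinates and classified into the 12 ordered substitutions or indels,
from which the transition/transversion ratio (reported as 2xTs/Tv) is
derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .coverage import PileupColumn
from .genome import PromoterWindow, to_relative

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
TRANSITIONS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))
TRANSVERSIONS = (
    ("A", "C"), ("A", "T"), ("C", "A"), ("C", "G"),
    ("G", "C"), ("G", "T"), ("T", "A"), ("T", "G"),
)
SUBSTITUTIONS = TRANSITIONS + TRANSVERSIONS

__all__ = [
    "VcfRecord",
    "PromoterVariant",
    "ChangeSpectrum",
    "read_vcf",
    "write_vcf",
    "mine_variants",
    "call_from_pileup",
    "calls_by_coverage",
    "change_spectrum",
    "tstv_ratio",
    "indel_base_context",
]


@dataclass(frozen=True)
class VcfRecord:
    """A minimal normalized VCF record (one alt allele)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int | None = None  # from INFO/DP or FORMAT/DP when present

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PromoterVariant:
    """A variant placed in a promoter window, in TSS-relative coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    rel: int
    depth: int | None
    vclass: str = field(init=False)  # "SNP" or "indel"
    change: tuple[str, str] | None = field(init=False)
    indel_len: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.ref) == 1 and len(self.alt) == 1:
            object.__setattr__(self, "vclass", "SNP")
            object.__setattr__(self, "change", (self.ref.upper(), self.alt.upper()))
            object.__setattr__(self, "indel_len", 0)
        else:
            object.__setattr__(self, "vclass", "indel")
            object.__setattr__(self, "change", None)
            object.__setattr__(self, "indel_len", abs(len(self.ref) - len(self.alt)))

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ChangeSpectrum:
    """Counts for the 12 ordered substitutions plus indels."""

    substitutions: dict[tuple[str, str], int]
    indels: int = 0

    def __post_init__(self) -> None:
        self.substitutions = {
            s: int(self.substitutions.get(s, 0)) for s in SUBSTITUTIONS
        }
        if any(v < 0 for v in self.substitutions.values()) or self.indels < 0:
            raise ValueError("counts must be >= 0")

    @property
    def ts(self) -> int:
        return sum(self.substitutions[s] for s in TRANSITIONS)

    @property
    def tv(self) -> int:
        return sum(self.substitutions[s] for s in TRANSVERSIONS)

    @property
    def snp_total(self) -> int:
        return self.ts + self.tv

    @property
    def total(self) -> int:
        return self.snp_total + self.indels

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"change": f"{a}-{b}", "count": self.substitutions[(a, b)]}
            for a, b in SUBSTITUTIONS
        ]
        rows.append({"change": "indel", "count": self.indels})
        return pd.DataFrame(rows)


def tstv_ratio(spectrum: ChangeSpectrum, ndigits: int = 2) -> float | None:
    """The doubled transition/transversion ratio, 2 x Ts / Tv, to 2 dp.

    Returns None when Tv is zero (the ratio is undefined, not infinite).
    """
    if spectrum.tv == 0:
        return None
    return round(2.0 * spectrum.ts / spectrum.tv, ndigits)


def change_spectrum(variants: Iterable[PromoterVariant]) -> ChangeSpectrum:
    subs = dict.fromkeys(SUBSTITUTIONS, 0)
    indels = 0
    for v in variants:
        if v.vclass == "SNP":
            if v.change not in subs:
                raise ValueError(f"non-ACGT substitution {v.change}")
            subs[v.change] += 1
        else:
            indels += 1
    return ChangeSpectrum(subs, indels)


# ---------------------------------------------------------------------------
# VCF IO (pysam-backed)

def read_vcf(path: str) -> Iterator[VcfRecord]:
    """Stream normalized records from a VCF; multi-allelic sites are split
    per alt allele and symbolic/breakend alleles are skipped with a warning.
    Site depth is taken from INFO/DP when present, else the first sample's
    FORMAT/DP.
    """
    import pysam

    with pysam.VariantFile(path) as vf:
        for rec in vf:
            depth = None
            if "DP" in rec.info:
                dp = rec.info["DP"]
                depth = int(dp[0] if isinstance(dp, tuple) else dp)
            elif rec.samples and "DP" in rec.samples[0]:
                dp = rec.samples[0]["DP"]
                if dp is not None:
                    depth = int(dp)
            for alt in rec.alts or ():
                if alt is None or alt.startswith("<") or "[" in alt or "]" in alt:
                    warnings.warn(
                        f"skipping symbolic allele {alt!r} at "
                        f"{rec.chrom}:{rec.pos}"
                    )
                    continue
                yield VcfRecord(rec.chrom, rec.pos, rec.ref.upper(),
                                alt.upper(), depth)


def write_vcf(
    variants: Sequence[PromoterVariant],
    path: str,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Re-emit retained promoter variants as VCF 4.2 with INFO tags
    GENE, RELPOS and VCLASS."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n')
        fh.write('##INFO=<ID=RELPOS,Number=1,Type=Integer,'
                 'Description="TSS-relative position">\n')
        fh.write('##INFO=<ID=VCLASS,Number=1,Type=String,'
                 'Description="SNP or indel">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
            info = [f"GENE={v.gene_id}", f"RELPOS={v.rel}", f"VCLASS={v.vclass}"]
            if v.depth is not None:
                info.insert(0, f"DP={v.depth}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                + ";".join(info) + "\n"
            )


# ---------------------------------------------------------------------------
# mining and calling

def _primary_trees(windows: Sequence[PromoterWindow]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        if w.primary:
            trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end + 1, w)
    return trees


def mine_variants(
    records: Iterable[VcfRecord] | str,
    windows: Sequence[PromoterWindow],
    depth_source: Mapping[tuple[str, int], int] | None = None,
    min_depth: int = 4,
    core_only: bool = False,
) -> list[PromoterVariant]:
    """Filter VCF records into promoter windows under the minimum-depth rule.

    A record is retained when its position lies in a (primary) promoter
    window — restricted to the core sub-window when *core_only* — and its
    site depth is at least *min_depth*.  Depth comes from the record's DP
    field when present, else from *depth_source*, a mapping of
    (chrom, pos) to promoter-mapped depth (e.g. built from a pileup);
    records with no depth from either source are dropped under the rule.
    """
    if isinstance(records, str):
        records = read_vcf(records)
    trees = _primary_trees(windows)
    out: list[PromoterVariant] = []
    for rec in records:
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        hits = tree.at(rec.pos)
        if not hits:
            continue
        w: PromoterWindow = next(iter(hits)).data
        rel = to_relative(w, rec.pos)
        if core_only and not (w.core_lo <= rel <= w.core_hi):
            continue
        depth = rec.depth
        if depth is None and depth_source is not None:
            depth = depth_source.get((rec.chrom, rec.pos))
        if depth is None or depth < min_depth:
            continue
        out.append(PromoterVariant(rec.chrom, rec.pos, rec.ref, rec.alt,
                                   w.gene_id, rel, depth))
    return out


def call_from_pileup(
    pileup: Iterable[PileupColumn],
    windows: Sequence[PromoterWindow],
    reference: Mapping[str, str] | None = None,
    ref_bases: Mapping[tuple[str, int], str] | None = None,
    min_depth: int = 4,
    alt_min: int = 2,
    alt_frac: float = 0.2,
) -> list[PromoterVariant]:
    """Call SNPs from pileup base counts inside promoter windows.

    A SNP is emitted where depth >= *min_depth* and some non-reference base
    has count >= *alt_min* and fraction >= *alt_frac* of depth.  The
    reference base comes from *reference* (chrom -> sequence string, e.g. a
    pyfaidx Fasta) or *ref_bases* ((chrom, pos) -> base); positions whose
    reference base is unknown are skipped with a warning.
    """
    trees = _primary_trees(windows)
    out: list[PromoterVariant] = []
    for col in pileup:
        tree = trees.get(col.chrom)
        if tree is None:
            continue
        hits = tree.at(col.pos)
        if not hits or col.depth < min_depth:
            continue
        ref = None
        if ref_bases is not None:
            ref = ref_bases.get((col.chrom, col.pos))
        elif reference is not None:
            ref = str(reference[col.chrom][col.pos - 1]).upper()
        if ref not in ("A", "C", "G", "T"):
            warnings.warn(f"unknown reference base at {col.chrom}:{col.pos}; skipped")
            continue
        w: PromoterWindow = next(iter(hits)).data
        for base in ("A", "C", "G", "T"):
            if base == ref:
                continue
            n = col.base_counts.get(base, 0)
            if n >= alt_min and n / col.depth >= alt_frac:
                out.append(PromoterVariant(
                    col.chrom, col.pos, ref, base,
                    w.gene_id, to_relative(w, col.pos), col.depth,
                ))
    return out


def calls_by_coverage(
    variants: Iterable[PromoterVariant],
    thresholds: Sequence[int] = range(1, 11),
) -> dict[int, int]:
    """Number of variants whose site depth reaches each coverage threshold.

    Counts are non-increasing in the threshold; variants without a depth
    are excluded from every threshold.
    """
    depths = [v.depth for v in variants if v.depth is not None]
    return {k: sum(d >= k for d in depths) for k in thresholds}


def indel_base_context(
    variants: Iterable[PromoterVariant],
    reference: Mapping[str, str],
) -> dict[str, int]:
    """Reference base at each indel's anchor position (VCF POS, left-aligned)."""
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for v in variants:
        if v.vclass != "indel":
            continue
        contig = reference[v.chrom]
        if v.pos > len(contig):
            raise IndexError(f"position {v.pos} beyond contig {v.chrom}")
        base = str(contig[v.pos - 1]).upper()
        if base in counts:
            counts[base] += 1
    return counts
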