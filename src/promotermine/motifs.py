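"""Core-promoter motif scanning and variant-motif intersection.

Four conserved core-promoter elements are built in as IUPAC degenerate
consensus strings — BRE (SSRCGCC), the TATA box (TATAWAAR), the initiator
INR (YYANWYY) and the downstream promoter element DPE (RGWYV) — and scanned
across the core window on both strands.  Transcription-factor binding
sites are handled through JASPAR position frequency matrices with standard
log-odds scoring.  Hits are reported wherever they occur in the core
window, not only at textbook positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome import rel_shift, _revcomp
from .variants import PromoterVariant

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

__all__ = [
    "ConsensusMotif",
    "MotifHit",
    "PFM",
    "BUILTIN_MOTIFS",
    "match_consensus",
    "scan_motifs",
    "intersect_variants",
    "read_jaspar",
    "pfm_scan",
    "position_tolerance",
]


@dataclass(frozen=True)
class ConsensusMotif:
    """A named IUPAC degenerate consensus pattern."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC symbols in pattern: {sorted(bad)}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)


BUILTIN_MOTIFS = (
    ConsensusMotif("BRE", "SSRCGCC"),
    ConsensusMotif("TATA", "TATAWAAR"),
    ConsensusMotif("INR", "YYANWYY"),
    ConsensusMotif("DPE", "RGWYV"),
)


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence in TSS-relative coordinates (inclusive span).

    ``sequence`` is always the top-strand (TSS-relative frame) sequence of
    the span; ``strand`` records which strand the motif matched on.
    """

    gene_id: str
    motif: str
    rel_start: int
    rel_end: int
    strand: str
    sequence: str

    def span(self) -> range:
        """Relative positions covered, skipping 0."""
        return _rel_span(self.rel_start, self.rel_end)


def _rel_span(lo: int, hi: int) -> range:
    # dense offsets so the no-zero gap is handled once
    off = lambda r: r - 1 if r > 0 else r  # noqa: E731
    return range(off(lo), off(hi) + 1)


def match_consensus(seq: str, motif: ConsensusMotif) -> bool:
    """True iff *seq* realizes the motif position-by-position.

    Length must equal the pattern length; sequences containing ambiguous
    bases never match (with a warning).
    """
    seq = seq.upper()
    if len(seq) != len(motif.pattern):
        raise ValueError(
            f"sequence length {len(seq)} != pattern length {len(motif.pattern)}"
        )
    if set(seq) - {"A", "C", "G", "T"}:
        warnings.warn(f"ambiguous bases in sequence {seq!r}; no match")
        return False
    return all(b in IUPAC[p] for b, p in zip(seq, motif.pattern))


def scan_motifs(
    seq: str,
    rel_lo: int,
    motifs: Sequence[ConsensusMotif] = BUILTIN_MOTIFS,
    gene_id: str = "",
    both_strands: bool = True,
) -> list[MotifHit]:
    """All sliding-window motif matches in a TSS-relative-frame sequence.

    *seq* starts at relative position *rel_lo* (typically the core window,
    -100).  Reverse-strand hits are found by matching the reverse
    complement of the pattern on the top strand, and are reported in
    top-strand coordinates with ``strand='-'`` and the top-strand sequence.
    """
    seq = seq.upper()
    hits: list[MotifHit] = []
    for motif in motifs:
        L = len(motif.pattern)
        patterns = [("+", motif.pattern)]
        if both_strands:
            rc = _revcomp(motif.pattern)
            if rc != motif.pattern:
                patterns.append(("-", rc))
        for i in range(len(seq) - L + 1):
            window = seq[i: i + L]
            if set(window) - {"A", "C", "G", "T"}:
                continue
            start = rel_shift(rel_lo, i)
            end = rel_shift(rel_lo, i + L - 1)
            for strand, pat in patterns:
                if all(b in IUPAC[p] for b, p in zip(window, pat)):
                    hits.append(MotifHit(gene_id, motif.name, start, end,
                                         strand, window))
    return hits


def intersect_variants(
    variants: Iterable[PromoterVariant],
    hits: Sequence[MotifHit],
) -> list[tuple[PromoterVariant, MotifHit]]:
    """Pair each variant with every motif hit it falls in (same gene frame).

    A SNP intersects when its relative position lies within the hit span;
    an indel when any base of its reference span does.
    """
    pairs: list[tuple[PromoterVariant, MotifHit]] = []
    for v in variants:
        vspan = set(_rel_span(v.rel, rel_shift(v.rel, max(0, len(v.ref) - 1))))
        for h in hits:
            if h.gene_id and v.gene_id and h.gene_id != v.gene_id:
                continue
            if vspan & set(h.span()):
                pairs.append((v, h))
    return pairs


# ---------------------------------------------------------------------------
# JASPAR position frequency matrices

@dataclass
class PFM:
    """A position frequency matrix: per-column base counts (rows A,C,G,T)."""

    matrix_id: str
    name: str
    counts: np.ndarray  # shape (4, L)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (rows A,C,G,T)")
        if self.counts.shape[1] < 1:
            raise ValueError("matrix must have at least one column")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every column must have a positive total")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def log_odds(self, pseudocount: float = 1.0) -> np.ndarray:
        """Per-base log2 odds vs a uniform 0.25 background."""
        c = self.counts + pseudocount
        p = c / c.sum(axis=0, keepdims=True)
        return np.log2(p / 0.25)


def read_jaspar(path: str) -> list[PFM]:
    """Read PFMs from JASPAR text format via Bio.motifs.

    Format: a ``>ID NAME`` header followed by four bracketed count rows
    (A, C, G, T).  Malformed rows raise a parse error naming the file.
    """
    from Bio import motifs as bio_motifs

    out: list[PFM] = []
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
            for m in records:
                counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
                out.append(PFM(m.matrix_id or m.name, m.name or m.matrix_id, counts))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed JASPAR matrix in {path}: {exc}") from exc
    return out


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def pfm_scan(
    seq: str,
    pfm: PFM,
    min_score: float = 0.8,
    rel_lo: int | None = None,
    gene_id: str = "",
    pseudocount: float = 1.0,
) -> list[dict]:
    """Scan a sequence with a PFM using log-odds scoring.

    The threshold *min_score* is a fraction (in [0, 1]) of the maximum
    achievable log-odds score.  Returns one dict per hit with the start
    offset (and TSS-relative start when *rel_lo* is given), the raw score
    and the score fraction.
    """
    if not (0.0 <= min_score <= 1.0):
        raise ValueError("min_score must be in [0, 1]")
    seq = seq.upper()
    lod = pfm.log_odds(pseudocount)
    max_score = float(lod.max(axis=0).sum())
    hits: list[dict] = []
    L = pfm.length
    for i in range(len(seq) - L + 1):
        window = seq[i: i + L]
        if set(window) - set(_BASE_INDEX):
            continue
        score = float(sum(lod[_BASE_INDEX[b], j] for j, b in enumerate(window)))
        frac = score / max_score if max_score > 0 else (1.0 if score == max_score else 0.0)
        if frac >= min_score - 1e-12:
            hit = {
                "matrix_id": pfm.matrix_id,
                "name": pfm.name,
                "offset": i,
                "sequence": window,
                "score": score,
                "score_frac": frac,
            }
            if rel_lo is not None:
                hit["rel_start"] = rel_shift(rel_lo, i)
                hit["rel_end"] = rel_shift(rel_lo, i + L - 1)
            hits.append(hit)
    return hits


def position_tolerance(pfm: PFM, column: int) -> dict:
    """How constrained one PFM column is.

    Reports the dominant-base frequency and the number of bases with
    nonzero counts; a column where only two bases ever occur has a
    tolerated-base count of 2.  This count is an interpretation of
    per-position tolerance, flagged as such in CLI output.
    """
    if not (0 <= column < pfm.length):
        raise IndexError(f"column {column} out of range for length {pfm.length}")
    col = pfm.counts[:, column]
    total = col.sum()
    dominant_i = int(col.argmax())
    return {
        "column": column,
        "dominant_base": "ACGT"[dominant_i],
        "dominant_frequency": float(col[dominant_i] / total),
        "n_tolerated_bases": int((col > 0).sum()),
    }
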