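# Methods

## Coordinate model

All internal coordinates are 1-based and closed. TSS-relative coordinates
put the transcription start site at +1 with no position 0, matching
standard promoter nomenclature: −1 is the base immediately upstream, and a
window from −500 to +100 spans exactly 600 bases. For a plus-strand gene
with TSS *t*, relative position *r* maps to the genomic position
*t + r − 1* (for *r* > 0) or *t + r* (for *r* < 0); minus-strand genes
mirror this about the TSS, so "upstream" is a higher genomic coordinate.
The mapping is a bijection on each window and round-trips exactly — a
property the suite fuzzes on both strands.

BED input is converted from 0-based half-open on read (TSS = interval
start for plus-strand genes, interval end for minus-strand); GFF3 is
already 1-based. Windows that would extend below position 1 are truncated
and flagged.

Where two promoter windows overlap on the same chromosome, the first gene
in annotation order claims the bases: its window stays `primary` and is
used for base attribution and variant assignment, while later overlapping
windows are retained (flagged non-primary) for per-gene reporting. This
first-in-file rule is the only deterministic reading of "use the first
gene" and keeps reruns reproducible.

## Coverage profiling

"Covered bases" are depth-weighted: a position with depth *d* contributes
*d* bases, so the region tally sums to the aligned read-base total. An
alternative — counting each covered position once — would measure breadth
rather than volume; the depth-weighted reading is the one that makes a
promoter fraction of ~1–2% of a read-base total meaningful, and is what
the tally reports. Classification precedence is promoter > exon > intron >
intergenic, evaluated per position: a base inside a promoter window that
also overlaps an annotated first exon counts as promoter. Introns are
positions inside a gene's exon span but outside its exons; chromosomes
absent from the annotation are counted intergenic with a warning.

Detection rates are computed per 50-bp TSS-relative bin, from the
downstream end (+100..+51) toward upstream (−451..−500). A gene counts as
detected in a bin iff at least one position of the bin reaches the depth
threshold (default 1); the threshold is a flag so stricter definitions can
be tested. Rates are percentages of all annotated genes, reported to one
decimal; cross-sample averages are arithmetic means of the per-sample
percentages (two decimals for region fractions, one for detection rates).

## Variant mining

The mining rule retains a VCF record when its position lies in a primary
promoter window — optionally restricted to the core sub-window, default
−100..+100 — and its site depth is at least `min_depth` (default 4
sequences, the point below which call counts inflate with likely
sequencing-error artifacts). Site depth comes from the record's DP field
when present; otherwise a caller-supplied pileup depth map is consulted,
restricted to window-overlapping positions. Records with no depth from
either source fail the rule rather than passing silently.

Variant identity is the exact key (chrom, pos, ref, alt) everywhere,
including cross-group comparisons; indels should be left-normalized
upstream so keys are comparable. Multi-allelic records are split per alt;
symbolic alleles are skipped with a warning. A SNP has ref and alt of
length 1; anything else is an indel with length |len(ref) − len(alt)|.
The indel anchor base is the reference base at POS (VCF left-aligned
convention).

The change spectrum counts the 12 ordered substitutions; transitions are
A↔G and C↔T. The ratio is reported as 2×Ts/Tv (two decimals), the doubled
form used for these cohort spectra; when Tv = 0 the ratio is undefined and
returned as `None`, never infinity.

The bundled pileup caller (depth ≥ 4, alt count ≥ 2, alt fraction ≥ 0.2 by
default) exists so the synthetic path is testable end to end without an
external caller; `alt_min` and `alt_frac` are plain artifact defaults with
no empirical calibration and are configurable. It is not a substitute for
a production caller: no genotype likelihoods, no realignment, no quality
modelling.

## Motif and TFBS annotation

The four built-in core-promoter elements are the IUPAC consensus strings
BRE `SSRCGCC`, TATA box `TATAWAAR`, INR `YYANWYY` and DPE `RGWYV`. A
sequence realizes a motif iff every base falls in the IUPAC class at its
position; sequences with ambiguous bases never match. Scanning slides over
the core window on the top strand and, by default, also matches the
reverse-complemented pattern (bottom-strand occurrences), always reporting
top-strand coordinates and the top-strand sequence with the hit strand
recorded. Hits are reported wherever they occur, not only at textbook
positions — variant-bearing motif instances are routinely found outside
the conventional locations, and DPE's 5-base pattern in particular is
unspecific enough that many hits are expected by chance; no random-hit
correction is applied.

JASPAR PFMs are parsed with Biopython's JASPAR reader. Scoring is log-odds
against a uniform 0.25 background with a +1 pseudocount, thresholded at a
fraction of the maximum achievable score (default 0.8) — the standard
JASPAR-compatible choice, configurable. Per-column tolerance is summarized
as the dominant-base frequency and the number of bases with nonzero
counts; the latter operationalizes "how many bases a position tolerates"
and is labelled an interpretation in output.

## Group comparison

Each group's VCFs are mined under the same rules and assembled into a
boolean incidence matrix; the sharing spectrum counts variants present in
exactly *k* of *N* individuals. Groups are compared per level with the
closed-form 2×2 chi-square without continuity correction (1 df) on
counts[k] vs (total − counts[k]); identical spectra give statistic 0 and
p = 1, and a degenerate table (zero column margin) is treated the same
way. No multiple-testing correction is applied across levels, matching how
such per-level tables are usually presented; a Bonferroni column is
emitted alongside for the reader. The grand-total row compares the two
group totals against their pooled sum with the same statistic. Stratum
partitions ("individualized" = k of exactly 1, "common-in-all" = k = N)
are set operations on variant keys.

## Synthetic data generator

The generator emulates the data features the method depends on, at desk
scale: a random genome (2 chromosomes × 80 kb by default), 100 evenly
spaced genes with random strand, per-sample pileups whose depth at
relative position *r* is Poisson with mean λ·exp(−decay·d(r)), where d is
the distance upstream of the downstream window end (+100), and two cohorts
of 27 individuals with planted core-window variants.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| window / core | −500..+100 / −100..+100 | the analysis windows of the method |
| `lambda_max` | 20 reads | a typical off-target promoter peak depth |
| `decay` | 0.004 /base | ~9% of peak depth at −500, the observed decay shape |
| `n_individuals` | 27 per group | the cohort size the comparison targets |
| `indel_fraction` | 0.28 | the indel share observed in a single-genome call set (81/291) |
| `ts_tv_target` | 1.5 | doubled ratio 3.0, inside the 3.07–3.51 cohort range |
| `depth_low..depth_high` | 5..30 | uniform per-carrier site depth, all above the depth-4 rule |
| sharing profile | ∝ 1/k | mostly private variants with a thin shared tail, the observed shape |
| `cross_group_overlap` | 0.1 | a minority of variant keys shared between groups |

Variant plants choose distinct genomic sites within core windows of
primary-attribution genes, take the reference base from the generated
genome, and draw the alternate as the transition partner with probability
r/(r+1) for Ts:Tv target r, else one of the two transversions uniformly.
Indels are deletions or insertions of 2–10 bases anchored at the site.
Sharing is planted exactly: a variant at level *k* is written into *k*
randomly chosen individuals' VCFs, so the spectrum recomputed from the
VCFs equals the configured profile identically (the suite asserts this).
The `n_low_depth` knob plants a fixed number of variants whose carriers
all fall below the depth rule, for filter tests; it defaults to 0.

A single `numpy` Generator seeded from the config drives every draw in a
documented order, so a fixed seed yields byte-identical output files.

What the generator does **not** emulate: sequencing errors and base
qualities, mappability and GC capture bias, linkage between nearby
variants, multiple TSS per gene, and realistic allele-frequency spectra.
Passing tests on this data show the pipeline's bookkeeping, coordinate
arithmetic and statistics are correct — they do not show robustness to
alignment artifacts or caller noise on real exomes.

## Numerical and edge-case choices

- Rounding uses Python's `round` at the precision of each report (ratios
  2 dp, detection rates 1 dp, region percentages 2 dp).
- Ts/Tv with zero transversions is `None` (undefined), and the CLI prints
  "undefined".
- Promoter windows running off a contig start are clipped to position 1
  and flagged `truncated`.
- Chi-square p-values use `scipy.stats.chi2.sf`; the statistic itself is
  the closed form, cross-checked in tests against
  `scipy.stats.chi2_contingency(correction=False)`.
- Problem sizes in the bundled end-to-end runs (100 genes, 5,000 variants
  per group, 27+27 individuals, ~10^4 plants) were chosen so the doubled
  Ts/Tv of the plants concentrates within a few percent of its target
  while a full run stays in the seconds range.

## Known limitations

- A single canonical TSS per gene; genes with multiple start sites need
  one row per TSS in the annotation.
- The "first gene wins" overlap rule is order-dependent by design; sort
  your annotation deliberately.
- The region tally is read-base-weighted; a distinct-position variant of
  the tally is not implemented.
- PFM "tolerance" is a count of nonzero-frequency bases, one defensible
  reading of per-position constraint among several.
- Cross-group key matching assumes left-normalized indels; the package
  does not itself normalize.
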