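"""Variant mining, the pileup caller, and change spectra / Ts-Tv."""

import numpy as np
import pytest

from promotermine.coverage import PileupColumn
from promotermine.genome import GeneModel, build_windows
from promotermine.variants import (
    SUBSTITUTIONS, ChangeSpectrum, PromoterVariant, VcfRecord,
    calls_by_coverage, call_from_pileup, change_spectrum,
    indel_base_context, mine_variants, read_vcf, tstv_ratio, write_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=100000>\n"
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


class TestMineVariants:
    def test_retained_variant_annotated_with_relative_position(self, windows):
        rec = VcfRecord("chr1", 9_962, "C", "G", depth=10)
        out = mine_variants([rec], windows)
        assert len(out) == 1
        v = out[0]
        assert (v.gene_id, v.rel, v.vclass, v.change) == \
            ("gplus", -38, "SNP", ("C", "G"))

    def test_depth_threshold_boundary(self, windows):
        recs = [VcfRecord("chr1", 9_962, "C", "G", depth=3),
                VcfRecord("chr1", 9_963, "C", "G", depth=4)]
        out = mine_variants(recs, windows, min_depth=4)
        assert [v.pos for v in out] == [9_963]

    def test_filter_monotone_in_min_depth(self, rng, windows):
        recs = [
            VcfRecord("chr1", int(p), "A", "G", depth=int(d))
            for p, d in zip(rng.integers(9_500, 10_100, size=200),
                            rng.integers(1, 12, size=200))
        ]
        keys = {
            k: {v.key for v in mine_variants(recs, windows, min_depth=k)}
            for k in range(1, 8)
        }
        for k in range(2, 8):
            assert keys[k] <= keys[k - 1]

    def test_core_only_restricts_to_core_window(self, windows):
        recs = [VcfRecord("chr1", 9_962, "C", "G", depth=9),   # rel -38
                VcfRecord("chr1", 9_700, "C", "G", depth=9)]   # rel -300
        out = mine_variants(recs, windows, core_only=True)
        assert [v.rel for v in out] == [-38]

    def test_depth_from_pileup_when_record_lacks_dp(self, windows):
        recs = [VcfRecord("chr1", 9_962, "C", "G", depth=None)]
        assert mine_variants(recs, windows) == []
        out = mine_variants(recs, windows,
                            depth_source={("chr1", 9_962): 8})
        assert out[0].depth == 8

    def test_planted_bookkeeping_below_threshold_dropped(self, rng, windows):
        depths = [3] * 12 + [10] * 38
        rng.shuffle(depths)
        recs = [VcfRecord("chr1", 9_500 + i, "A", "T", depth=d)
                for i, d in enumerate(depths)]
        assert len(mine_variants(recs, windows, min_depth=4)) == 38

    def test_multiallelic_split_and_symbolic_skipped(self, tmp_path, windows):
        path = tmp_path / "x.vcf"
        path.write_text(
            VCF_HEADER
            + "chr1\t9962\t.\tC\tG,T\t.\tPASS\tDP=9\n"
            + "chr1\t9970\t.\tC\t<DEL>\t.\tPASS\tDP=9\n"
        )
        with pytest.warns(UserWarning, match="symbolic"):
            recs = list(read_vcf(str(path)))
        out = mine_variants(recs, windows)
        assert sorted(v.alt for v in out) == ["G", "T"]

    def test_vcf_round_trip_keeps_info_tags(self, tmp_path, windows):
        v = mine_variants([VcfRecord("chr1", 9_962, "C", "G", 10)], windows)
        path = tmp_path / "out.vcf"
        write_vcf(v, str(path), contigs={"chr1": 100_000})
        text = path.read_text()
        assert "GENE=gplus" in text and "RELPOS=-38" in text
        back = list(read_vcf(str(path)))
        assert back[0].key == ("chr1", 9_962, "C", "G")
        assert back[0].depth == 10


class TestCallFromPileup:
    REF = {("chr1", 9_962): "A", ("chr1", 9_963): "A"}

    def test_boundary_call_on_defaults(self, windows):
        cols = [PileupColumn("chr1", 9_962, 4, {"A": 2, "G": 2})]
        out = call_from_pileup(cols, windows, ref_bases=self.REF)
        assert [(v.ref, v.alt, v.rel) for v in out] == [("A", "G", -38)]

    def test_low_alt_fraction_not_called(self, windows):
        cols = [PileupColumn("chr1", 9_962, 20, {"A": 19, "T": 1})]
        assert call_from_pileup(cols, windows, ref_bases=self.REF) == []

    def test_unknown_reference_base_skipped_with_warning(self, windows):
        cols = [PileupColumn("chr1", 9_970, 10, {"G": 10})]
        with pytest.warns(UserWarning, match="reference"):
            assert call_from_pileup(cols, windows, ref_bases=self.REF) == []

    def test_planted_variants_recovered_no_false_calls(self, rng, windows):
        genome = {"chr1": "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, size=50_000)])}
        plants = {}
        cols = []
        for i, pos in enumerate(range(9_500, 9_700)):
            ref = genome["chr1"][pos - 1]
            if i % 10 == 0:  # plant an alt meeting thresholds
                alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
                plants[pos] = (ref, alt)
                cols.append(PileupColumn("chr1", pos, 10, {ref: 5, alt: 5}))
            else:  # clean reference with sub-threshold noise
                noise = "G" if ref != "G" else "C"
                cols.append(PileupColumn("chr1", pos, 10, {ref: 9, noise: 1}))
        out = call_from_pileup(cols, windows, reference=genome)
        assert {v.pos: (v.ref, v.alt) for v in out} == plants


class TestCallsByCoverage:
    def test_direct_enumeration(self):
        vs = [PromoterVariant("chr1", i, "A", "G", "g", -1, d)
              for i, d in enumerate([1, 1, 2, 3, 4, 10], start=1)]
        counts = calls_by_coverage(vs, thresholds=range(1, 5))
        assert counts == {1: 6, 2: 4, 3: 3, 4: 2}

    def test_constant_when_all_depths_high(self):
        vs = [PromoterVariant("chr1", i, "A", "G", "g", -1, 50)
              for i in range(5)]
        counts = calls_by_coverage(vs)
        assert set(counts.values()) == {5}

    def test_monotone_non_increasing(self, rng):
        vs = [PromoterVariant("chr1", i, "A", "G", "g", -1, int(d))
              for i, d in enumerate(rng.integers(1, 40, size=500), start=1)]
        counts = calls_by_coverage(vs, thresholds=range(1, 31))
        vals = [counts[k] for k in range(1, 31)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestChangeSpectrum:
    def test_spectrum_counts_partition_variants(self, rng):
        bases = "ACGT"
        vs = []
        for i in range(400):
            ref = bases[rng.integers(0, 4)]
            alt = bases[rng.integers(0, 4)]
            if alt == ref:
                vs.append(PromoterVariant("chr1", i + 1, ref, ref + "AT",
                                          "g", 5, 9))  # insertion
            else:
                vs.append(PromoterVariant("chr1", i + 1, ref, alt, "g", 5, 9))
        spec = change_spectrum(vs)
        n_snp = sum(1 for v in vs if v.vclass == "SNP")
        assert spec.snp_total == n_snp
        assert spec.total == len(vs)
        # brute-force purine/pyrimidine transition count
        pur = {"A", "G"}
        ts = sum(1 for v in vs if v.vclass == "SNP"
                 and (v.ref in pur) == (v.alt in pur))
        assert spec.ts == ts
        if spec.tv:
            assert tstv_ratio(spec) == round(2 * ts / spec.tv, 2)

    def test_undefined_ratio_when_no_transversions(self):
        spec = change_spectrum(
            [PromoterVariant("chr1", 1, "A", "G", "g", 5, 9)])
        assert spec.ts == 1 and spec.tv == 0
        assert tstv_ratio(spec) is None

    def test_printed_cohort_column_reproduced(self):
        # shared-within-group spectrum of the first cohort
        counts = dict(zip(SUBSTITUTIONS, [11, 3, 7, 12, 3, 2, 0, 5, 4, 2, 2, 3]))
        spec = ChangeSpectrum(counts, indels=3)
        assert (spec.ts, spec.tv) == (33, 21)
        assert tstv_ratio(spec) == 3.14

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ChangeSpectrum({("A", "G"): -1})


class TestIndelContext:
    GENOME = {"chr1": "AACT" * 2_500}

    def test_no_indels_all_zero(self):
        assert indel_base_context([], self.GENOME) == \
            {"A": 0, "C": 0, "G": 0, "T": 0}

    def test_anchor_base_counts(self):
        vs = [PromoterVariant("chr1", p, self.GENOME["chr1"][p - 1] + "GG",
                              self.GENOME["chr1"][p - 1], "g", 5, 9)
              for p in (1, 2, 3, 4)]  # anchors A, A, C, T
        assert indel_base_context(vs, self.GENOME) == \
            {"A": 2, "C": 1, "G": 0, "T": 1}

    def test_matches_brute_force_on_random_sites(self, rng):
        positions = rng.integers(1, 10_000, size=300)
        vs = [PromoterVariant("chr1", int(p),
                              self.GENOME["chr1"][p - 1] + "A",
                              self.GENOME["chr1"][p - 1], "g", 5, 9)
              for p in positions]
        expect = {"A": 0, "C": 0, "G": 0, "T": 0}
        for p in positions:
            expect[self.GENOME["chr1"][p - 1]] += 1
        assert indel_base_context(vs, self.GENOME) == expect

    def test_position_beyond_contig_raises(self):
        v = PromoterVariant("chr1", 10_001, "AG", "A", "g", 5, 9)
        with pytest.raises(IndexError):
            indel_base_context([v], self.GENOME)
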