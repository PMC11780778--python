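import io

import numpy as np
import pytest

from equase.annotation import (
    HISTONE_MARKS,
    ConsequenceRecord,
    PeakIndex,
    PeakInterval,
    consequence_type_summary,
    filter_consequences,
    haplotype_region,
    mark_combination_summary,
    overlap_marks,
    read_peak_bed,
    read_vep_table,
    split_terms,
)
from equase.haplotypes import Haplotype, HetLocus
from helpers_oracles import brute_force_overlap


def record(*terms, chrom="chr1", pos=100, gene="G1"):
    return ConsequenceRecord(
        chrom=chrom, pos=pos, gene_id=gene, gene_symbol=gene,
        consequence_terms=frozenset(terms),
    )


class TestSplitTerms:
    def test_ampersand_and_comma(self):
        assert split_terms("splice_region_variant&intron_variant") == {
            "splice_region_variant",
            "intron_variant",
        }
        assert split_terms("missense_variant, synonymous_variant") == {
            "missense_variant",
            "synonymous_variant",
        }


class TestReadVepTable:
    VEP = (
        "#Uploaded_variation\tLocation\tAllele\tGene\tFeature\tFeature_type\tConsequence\tSYMBOL\n"
        "v1\tchr1:100\tG\tENSG1\tT1\tTranscript\tmissense_variant\tAPOE\n"
        "v1\tchr1:100\tG\tENSG1\tT2\tTranscript\tintron_variant\tAPOE\n"
        "v2\tchr2:55\tT\tENSG2\tT3\tTranscript\t3_prime_UTR_variant\tCLU\n"
    )

    def test_rows_merged_per_locus(self):
        records = read_vep_table(io.StringIO(self.VEP))
        by_pos = {(r.chrom, r.pos): r for r in records}
        assert by_pos[("chr1", 100)].consequence_terms == {
            "missense_variant",
            "intron_variant",
        }
        assert by_pos[("chr1", 100)].gene_symbol == "APOE"
        assert by_pos[("chr2", 55)].consequence_terms == {"3_prime_UTR_variant"}

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            read_vep_table(io.StringIO("Location\tGene\nchr1:5\tG\n"))


class TestFilterConsequences:
    def test_intron_only_removed(self):
        kept, removed = filter_consequences([record("intron_variant")])
        assert kept == [] and len(removed) == 1

    def test_intergenic_only_removed(self):
        kept, removed = filter_consequences([record("intergenic_variant")])
        assert len(removed) == 1

    def test_intron_and_intergenic_removed(self):
        kept, removed = filter_consequences(
            [record("intron_variant", "intergenic_variant")]
        )
        assert len(removed) == 1

    def test_exclusivity_fails_with_functional_term(self):
        kept, removed = filter_consequences(
            [record("intron_variant", "missense_variant")]
        )
        assert len(kept) == 1 and removed == []

    def test_utr_kept(self):
        kept, _ = filter_consequences([record("3_prime_UTR_variant")])
        assert len(kept) == 1

    def test_splice_compound_with_intron_kept(self):
        kept, _ = filter_consequences(
            [record("splice_region_variant", "intron_variant")]
        )
        assert len(kept) == 1

    def test_unknown_term_warns_and_keeps(self, caplog):
        with caplog.at_level("WARNING"):
            kept, removed = filter_consequences([record("mystery_variant")])
        assert len(kept) == 1 and removed == []
        assert "unknown consequence" in caplog.text

    def test_partition_and_idempotence(self):
        records = [
            record("intron_variant", pos=1),
            record("missense_variant", pos=2),
            record("intergenic_variant", pos=3),
            record("3_prime_UTR_variant", "intron_variant", pos=4),
        ]
        kept, removed = filter_consequences(records)
        assert len(kept) + len(removed) == len(records)
        assert set(id(r) for r in kept).isdisjoint(id(r) for r in removed)
        kept2, removed2 = filter_consequences(kept)
        assert kept2 == kept and removed2 == []


class TestConsequenceTypeSummary:
    def test_variant_type_fixture(self):
        records = (
            [record("3_prime_UTR_variant", pos=i) for i in range(335)]
            + [record("missense_variant", pos=1000 + i) for i in range(135)]
            + [record("synonymous_variant", pos=2000 + i) for i in range(134)]
            + [record("5_prime_UTR_variant", pos=3000 + i) for i in range(131)]
            + [record("stop_gained", pos=4000 + i) for i in range(39)]
        )
        assert len(records) == 774
        df = consequence_type_summary(records)
        by_combo = df.set_index("consequence_combination")
        assert by_combo.loc["3_prime_UTR_variant", "percent"] == 43.28
        assert by_combo.loc["missense_variant", "percent"] == 17.44
        assert by_combo.loc["synonymous_variant", "percent"] == 17.31
        assert by_combo.loc["5_prime_UTR_variant", "percent"] == 16.93

    def test_combination_joined_sorted(self):
        df = consequence_type_summary(
            [record("splice_region_variant", "intron_variant")]
        )
        assert df.iloc[0].consequence_combination == "intron_variant&splice_region_variant"
        assert df.iloc[0].percent == 100.00

    def test_empty(self):
        assert consequence_type_summary([]).empty


class TestHaplotypeRegion:
    def _hap(self, positions):
        alleles = [("A", "G"), ("C", "T"), ("G", "C"), ("T", "A")]
        loci = tuple(
            HetLocus("chr3", p, *alleles[i % 4]) for i, p in enumerate(positions)
        )
        return Haplotype(sample_id="s", tissue="t", block_id="b", loci=loci)

    def test_span(self):
        assert haplotype_region(self._hap([100, 250, 400])) == ("chr3", 100, 400)

    def test_single_locus(self):
        assert haplotype_region(self._hap([77])) == ("chr3", 77, 77)

    def test_order_invariance(self):
        assert haplotype_region(self._hap([400, 100, 250])) == ("chr3", 100, 400)


class TestOverlapMarks:
    def _peak(self, start, end, mark="H3K27ac", tissue="liver", sample="s1", chrom="chr1"):
        return PeakInterval(chrom=chrom, start=start, end=end, mark=mark,
                            tissue=tissue, sample=sample)

    def test_basic_overlap(self):
        index = PeakIndex([self._peak(150, 250)])
        assert overlap_marks(("chr1", 100, 200), index, "liver", "s1") == {"H3K27ac"}

    def test_adjacent_no_overlap(self):
        index = PeakIndex([self._peak(201, 300)])
        assert overlap_marks(("chr1", 100, 200), index, "liver", "s1") == set()

    def test_single_bp_touch_counts(self):
        index = PeakIndex([self._peak(200, 300)])
        assert overlap_marks(("chr1", 100, 200), index, "liver", "s1") == {"H3K27ac"}

    def test_tissue_and_sample_scoped(self):
        index = PeakIndex([self._peak(150, 250, tissue="heart")])
        assert overlap_marks(("chr1", 100, 200), index, "liver", "s1") == set()
        index2 = PeakIndex([self._peak(150, 250, sample="s2")])
        assert overlap_marks(("chr1", 100, 200), index2, "liver", "s1") == set()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        chroms = ["chr1", "chr2"]
        tissues = ["liver", "heart"]
        samples = ["s1", "s2"]
        peaks = []
        for _ in range(300):
            start = int(rng.integers(1, 50_000))
            peaks.append(
                (
                    chroms[rng.integers(2)],
                    start,
                    start + int(rng.integers(1, 2_000)),
                    HISTONE_MARKS[rng.integers(4)],
                    tissues[rng.integers(2)],
                    samples[rng.integers(2)],
                )
            )
        index = PeakIndex(PeakInterval(*p) for p in peaks)
        for _ in range(300):
            start = int(rng.integers(1, 50_000))
            region = (chroms[rng.integers(2)], start, start + int(rng.integers(1, 3_000)))
            tissue = tissues[rng.integers(2)]
            sample = samples[rng.integers(2)]
            assert overlap_marks(region, index, tissue, sample) == brute_force_overlap(
                region, peaks, tissue, sample
            )


class TestReadPeakBed:
    def test_bed_coordinates_converted(self):
        bed = io.StringIO("chr1\t99\t200\tH3K4me1\tliver\ts1\n")
        (peak,) = read_peak_bed(bed)
        assert (peak.start, peak.end) == (100, 200)

    def test_bed3_requires_labels(self):
        with pytest.raises(ValueError, match="labels missing"):
            read_peak_bed(io.StringIO("chr1\t0\t100\n"))

    def test_bed3_with_reader_labels(self):
        (peak,) = read_peak_bed(
            io.StringIO("chr1\t0\t100\n"), mark="H3K27me3", tissue="liver", sample="s1"
        )
        assert peak.mark == "H3K27me3"

    def test_track_lines_skipped(self):
        bed = io.StringIO("track name=x\n# comment\nchr1\t0\t10\tH3K27ac\tliver\ts1\n")
        assert len(read_peak_bed(bed)) == 1

    def test_unknown_mark_rejected(self):
        with pytest.raises(ValueError, match="unknown histone mark"):
            read_peak_bed(io.StringIO("chr1\t0\t10\tH3K9me3\tliver\ts1\n"))


class TestMarkCombinationSummary:
    def test_results_section_fixture(self):
        # 774 loci: 277 none, 128 exactly one mark, 369 with two marks
        mark_sets = (
            [set() for _ in range(277)]
            + [{"H3K27ac"} for _ in range(128)]
            + [{"H3K27ac", "H3K4me1"} for _ in range(369)]
        )
        summary = mark_combination_summary(mark_sets)
        assert summary.n_total == 774
        assert summary.n_with_any == 497
        assert summary.pct_with_any == 64.2
        assert summary.n_multi == 369
        assert summary.pct_multi_of_with == 74.2

    def test_exclusive_combinations_partition_with_any(self):
        rng = np.random.default_rng(11)
        mark_sets = [
            {m for m in HISTONE_MARKS if rng.random() < 0.4} for _ in range(500)
        ]
        summary = mark_combination_summary(mark_sets)
        assert sum(summary.exclusive_combinations.values()) == summary.n_with_any

    def test_no_peaks(self):
        summary = mark_combination_summary([set(), set()])
        assert summary.n_with_any == 0
        assert summary.per_mark == {m: 0 for m in HISTONE_MARKS}
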