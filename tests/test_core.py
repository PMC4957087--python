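"""Genome container, FASTA/GFF3 dialect, splicing, masking, summary math."""

import pytest

from mitokit import (
    AnnotationSet,
    GeneModel,
    Genome,
    Interval,
    cds_to_genomic,
    coverage_depth,
    gc_percent,
    genome_percent,
    mask_features,
    mean_read_length,
    read_annotation,
    read_fasta,
    splice_cds,
    summarize_genome,
    validation_accuracy,
    write_annotation,
    write_fasta,
)
from mitokit.core import interval_union_size, round_half_up


class TestFasta:
    def test_minimal_circular_record(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">g topology=circular\nACGT\n")
        (g,) = read_fasta(p)
        assert (g.id, len(g), g.topology) == ("g", 4, "circular")

    def test_two_records_in_file_order_default_linear(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">a\nAC\n>b\nGGTT\n")
        gs = read_fasta(p)
        assert [g.id for g in gs] == ["a", "b"]
        assert all(g.topology == "linear" for g in gs)

    def test_lowercase_sequence_is_uppercased(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">g\nacgt\n")
        assert read_fasta(p)[0].sequence == "ACGT"

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text("ACGT\n>g\nAC\n")
        with pytest.raises(ValueError, match=":1:"):
            read_fasta(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_fasta(p)

    def test_round_trip_byte_identity(self, tmp_path):
        genomes = [
            Genome("x", "ACGTN" * 37, "circular"),
            Genome("y", "A", "linear"),
        ]
        p = tmp_path / "rt.fasta"
        write_fasta(genomes, p)
        back = read_fasta(p)
        assert [(g.id, g.sequence, g.topology) for g in back] == [
            (g.id, g.sequence, g.topology) for g in genomes
        ]


TOY_GENOME = Genome("toy", "AAACGTCGTAAA" * 5, "linear")


def _gff(tmp_path, body: str):
    p = tmp_path / "a.gff3"
    p.write_text("##gff-version 3\n" + body)
    return p


class TestAnnotation:
    def test_single_exon_plus_gene(self, tmp_path):
        p = _gff(
            tmp_path,
            "toy\t.\tgene\t10\t30\t.\t+\t.\tID=g1;category=protein\n"
            "toy\t.\texon\t10\t30\t.\t+\t.\tParent=g1\n",
        )
        ann = read_annotation(p, TOY_GENOME)
        assert len(ann) == 1
        assert ann.by_id("g1").exons == [Interval(10, 30, "+")]

    def test_minus_strand_exons_in_coding_order(self, tmp_path):
        p = _gff(
            tmp_path,
            "toy\t.\tgene\t10\t50\t.\t-\t.\tID=g1;category=protein\n"
            "toy\t.\texon\t10\t20\t.\t-\t.\tParent=g1\n"
            "toy\t.\texon\t40\t50\t.\t-\t.\tParent=g1\n",
        )
        g = read_annotation(p, TOY_GENOME).by_id("g1")
        # coding order on - strand is rightmost exon first
        assert [e.start for e in g.exons] == [40, 10]

    def test_trans_spliced_gene_with_mixed_strands_accepted(self, tmp_path):
        p = _gff(
            tmp_path,
            "toy\t.\tgene\t5\t40\t.\t+\t.\tID=g1;category=protein;trans_spliced=true\n"
            "toy\t.\texon\t5\t10\t.\t+\t.\tParent=g1;coding_order=1\n"
            "toy\t.\texon\t30\t40\t.\t-\t.\tParent=g1;coding_order=2\n",
        )
        g = read_annotation(p, TOY_GENOME).by_id("g1")
        assert g.trans_spliced
        assert [e.strand for e in g.exons] == ["+", "-"]

    def test_exon_outside_genome_errors(self, tmp_path):
        p = _gff(
            tmp_path,
            "toy\t.\tgene\t10\t9999\t.\t+\t.\tID=g1\n"
            "toy\t.\texon\t10\t9999\t.\t+\t.\tParent=g1\n",
        )
        with pytest.raises(ValueError, match="outside genome"):
            read_annotation(p, TOY_GENOME)

    def test_duplicate_gene_id_errors(self, tmp_path):
        p = _gff(
            tmp_path,
            "toy\t.\tgene\t1\t5\t.\t+\t.\tID=g1\n"
            "toy\t.\tgene\t7\t9\t.\t+\t.\tID=g1\n",
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_annotation(p, TOY_GENOME)

    def test_annotation_round_trip(self, tmp_path, bundle):
        p = tmp_path / "rt.gff3"
        write_annotation(bundle.mt_ann, p)
        back = read_annotation(p, bundle.mt)
        for g0, g1 in zip(bundle.mt_ann.genes, sorted(back.genes, key=lambda g: [x.gene_id for x in bundle.mt_ann.genes].index(g.gene_id))):
            assert g0.exons == g1.exons
            assert g0.category == g1.category
            assert g0.trans_spliced == g1.trans_spliced


class TestSplicing:
    GENOME = Genome("g", "AAACGTCGTAAA")

    def test_plus_exon_is_substring(self):
        gene = GeneModel("g1", "g1", "protein", [Interval(5, 10, "+")])
        assert splice_cds(self.GENOME, gene) == "GTCGTA"

    def test_minus_exon_is_reverse_complement(self):
        gene = GeneModel("g1", "g1", "protein", [Interval(5, 10, "-")])
        assert splice_cds(self.GENOME, gene) == "TACGAC"

    def test_trans_spliced_concatenation(self):
        # 60-bp toy genome; manual concatenation is the oracle
        genome = Genome("g", "ATGAAA" + "T" * 20 + "CCCGGG" + "T" * 22 + "TTAGGG")
        gene = GeneModel(
            "t", "t", "protein",
            [Interval(1, 6, "+"), Interval(27, 32, "+")],
            trans_spliced=True,
        )
        assert splice_cds(genome, gene) == "ATGAAA" + "CCCGGG"

    def test_spliced_length_and_projection_identity(self, bundle):
        for g in bundle.mt_ann.genes:
            cds = splice_cds(bundle.mt, g)
            assert len(cds) == sum(e.span for e in g.exons)
            # projecting every CDS position back lands inside an exon, and
            # the genomic base (strand-adjusted) equals the CDS base
            for pos in range(1, len(cds) + 1, max(1, len(cds) // 7)):
                gpos = cds_to_genomic(g, pos)
                assert any(e.start <= gpos <= e.end for e in g.exons)


class TestMasking:
    def test_empty_annotation_unchanged(self):
        g = Genome("g", "ACGTACGT")
        ann = AnnotationSet("g", [])
        assert mask_features(g, ann, {"protein"}) == g.sequence

    def test_single_gene_masked(self):
        g = Genome("g", "AAAAA")
        ann = AnnotationSet(
            "g", [GeneModel("x", "x", "protein", [Interval(2, 4, "+")])]
        )
        assert mask_features(g, ann, {"protein"}) == "ANNNA"

    def test_overlapping_genes_mask_union(self):
        g = Genome("g", "A" * 30)
        ann = AnnotationSet(
            "g",
            [
                GeneModel("x", "x", "protein", [Interval(3, 12, "+")]),
                GeneModel("y", "y", "tRNA", [Interval(10, 20, "+")]),
            ],
        )
        masked = mask_features(g, ann, {"protein", "tRNA"})
        expected_n = len({p for p in range(3, 13)} | {p for p in range(10, 21)})
        assert masked.count("N") == expected_n
        assert len(masked) == len(g.sequence)


class TestSummary:
    def test_gc_all(self):
        assert gc_percent("GGCC") == 100.00

    def test_gc_with_n_in_denominator(self):
        assert gc_percent("GCNN") == 50.00

    @pytest.mark.parametrize(
        "bp,expected",
        [
            (35651, 6.8), (5541, 1.1), (11407, 2.2), (1054, 0.2), (506, 0.1),
            (38062, 7.3), (39780, 7.6), (48898, 9.3), (16668, 3.2), (2628, 0.5),
        ],
    )
    def test_feature_percentages_of_a_524797_bp_genome(self, bp, expected):
        assert genome_percent(bp, 524_797) == expected

    def test_summarize_counts_categories(self, bundle):
        s = summarize_genome(bundle.mt, bundle.mt_ann)
        by_feature = {r.feature: r for r in s.rows}
        n_protein = sum(1 for g in bundle.mt_ann if g.category == "protein")
        assert by_feature["protein coding"].count == n_protein
        assert by_feature["pseudogenes"].count == 1
        assert by_feature["cp-derived tRNA"].count == 1
        # cis intron bp from annotation geometry
        cis = by_feature["cis-spliced"]
        assert cis.count == 1 and cis.total_bp > 0

    def test_interval_union_oracle(self):
        ivs = [Interval(1, 10), Interval(5, 12), Interval(20, 20)]
        explicit = len(set(range(1, 11)) | set(range(5, 13)) | {20})
        assert interval_union_size(ivs) == explicit


class TestAssemblyArithmetic:
    def test_coverage_depth_of_the_filtered_reads(self):
        assert coverage_depth(31_112_098, 524_797) == 59

    def test_coverage_depth_trivial(self):
        assert coverage_depth(100, 100) == 1

    def test_mean_corrected_read_length(self):
        assert mean_read_length(42_623_117, 9_165) == 4651

    def test_mean_filtered_read_length(self):
        assert mean_read_length(31_112_098, 7_151) == 4351

    @pytest.mark.parametrize(
        "mm,bp,expected", [(1, 20_176, 99.995), (0, 100, 100.0), (50, 100, 50.0)]
    )
    def test_validation_accuracy(self, mm, bp, expected):
        assert validation_accuracy(mm, bp) == expected

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            coverage_depth(10, 0)
        with pytest.raises(ValueError):
            validation_accuracy(0, 0)

    def test_half_up_rounding(self):
        assert round_half_up(0.5) == 1.0
        assert round_half_up(2.5) == 3.0
        assert round_half_up(1.2345, 3) == 1.235
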