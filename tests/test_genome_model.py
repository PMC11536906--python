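import numpy as np
import pytest

from smorfreg.genome_model import (
    FootprintRead,
    GenomeInterval,
    GtfParseError,
    PsiteOffsetTable,
    PsiteTrack,
    TranscriptModel,
    AnnotationSet,
    assign_psites,
    extract_transcript_seq,
    parse_region,
    read_bed12,
    read_gtf,
    read_psite_table,
    span_codon_lengths,
    write_bed12,
    write_gtf,
    write_psite_table,
)
from conftest import random_transcript


class TestGenomeInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenomeInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomeInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomeInterval("", 0, 5)
        with pytest.raises(ValueError):
            GenomeInterval("chr1", 0, 5, "x")

    def test_length_and_printing(self):
        iv = GenomeInterval("chr1", 100, 200)
        assert len(iv) == 100
        assert iv.to_1based() == "chr1:101-200"

    def test_parse_region_roundtrip(self):
        iv = parse_region("chr6:32845552-32845740")
        assert (iv.start, iv.end) == (32845551, 32845740)
        assert iv.to_1based() == "chr6:32845552-32845740"

    def test_span_codon_lengths(self):
        d = span_codon_lengths(parse_region("chr1:1-9"))
        assert d == {"nt": 9, "aa_excl_stop": 3, "aa_incl_stop": 2}
        with pytest.raises(ValueError):
            span_codon_lengths(parse_region("chr1:1-10"))


class TestGtf:
    def test_coordinate_conversion(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        ann = read_gtf(p)
        exon = ann.transcripts["t1"].exons[0]
        assert (exon.start, exon.end) == (100, 200)
        assert len(exon) == 100

    def test_two_line_single_transcript(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            "# comment\n"
            'chr1\tx\texon\t1\t50\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        ann = read_gtf(p)
        assert len(ann) == 1
        assert len(ann.transcripts["t1"].exons) == 1

    def test_end_before_start_errors_with_line_number(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tx\texon\t1\t50\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\texon\t90\t60\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(GtfParseError, match="line 2"):
            read_gtf(p)

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text("chr1\texon\t1\t50\n")
        with pytest.raises(GtfParseError, match="line 1"):
            read_gtf(p)

    def test_overlapping_exons_rejected(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tx\texon\t1\t50\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\texon\t40\t80\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(ValueError, match="overlapping"):
            read_gtf(p)

    def test_biotype_fallback(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tx\texon\t1\t9\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        assert read_gtf(p).transcripts["t"].biotype == "other"

    def test_write_read_lossless(self, rng, tmp_path):
        txs = [random_transcript(rng, f"t{i}") for i in range(25)]
        for i, tx in enumerate(txs):
            tx.biotype = ["protein_coding", "lncRNA", "other"][i % 3]
        ann = AnnotationSet(txs)
        p = tmp_path / "round.gtf"
        write_gtf(ann, p)
        back = read_gtf(p)
        assert set(back.transcripts) == set(ann.transcripts)
        for tid, tx in ann.transcripts.items():
            b = back.transcripts[tid]
            assert b.exons == tx.exons
            assert b.strand == tx.strand
            assert b.biotype == tx.biotype


class TestTranscriptSeq:
    def test_plus_single_exon(self):
        tx = TranscriptModel("t", "g", "+", [GenomeInterval("c", 0, 6)])
        assert extract_transcript_seq({"c": "ATGCCC"}, tx) == "ATGCCC"

    def test_minus_single_exon_revcomp(self):
        tx = TranscriptModel("t", "g", "-", [GenomeInterval("c", 0, 6, "-")])
        assert extract_transcript_seq({"c": "ATGCCC"}, tx) == "GGGCAT"

    def test_two_exon_concatenation(self):
        # per-base oracle: exon bases concatenated in transcript order
        genome = {"c": "ATGxxxTAA".replace("x", "C")}
        tx = TranscriptModel(
            "t", "g", "+", [GenomeInterval("c", 0, 3), GenomeInterval("c", 6, 9)]
        )
        assert extract_transcript_seq(genome, tx) == "ATGTAA"

    def test_out_of_bounds(self):
        tx = TranscriptModel("t", "g", "+", [GenomeInterval("c", 0, 10)])
        with pytest.raises(ValueError):
            extract_transcript_seq({"c": "ACGT"}, tx)
        with pytest.raises(KeyError):
            extract_transcript_seq({"other": "ACGT"}, tx)


class TestCoordinateMapping:
    def test_plus_two_blocks(self, two_exon_plus):
        blocks = two_exon_plus.tx_to_genome(5, 15)
        assert [(b.start, b.end) for b in blocks] == [(105, 110), (120, 125)]

    def test_minus_first_bases(self, two_exon_minus):
        blocks = two_exon_minus.tx_to_genome(0, 5)
        assert [(b.start, b.end) for b in blocks] == [(125, 130)]

    def test_full_length_identity(self, two_exon_plus):
        blocks = two_exon_plus.tx_to_genome(0, two_exon_plus.length)
        assert blocks == two_exon_plus.exons

    def test_out_of_range(self, two_exon_plus):
        with pytest.raises(ValueError):
            two_exon_plus.tx_to_genome(0, 21)

    def test_intronic_position_is_none(self, two_exon_plus):
        assert two_exon_plus.genome_to_tx(115) is None

    def test_roundtrip_identity_random_transcripts(self, rng):
        # exhaustive per-base oracle over many random exon chains
        for i in range(300):
            tx = random_transcript(rng, f"t{i}")
            # forward per-base mapping oracle
            genomic_positions = []
            for b in tx.tx_to_genome(0, tx.length):
                genomic_positions.extend(range(b.start, b.end))
            if tx.strand == "-":
                oracle = []
                for e in reversed(tx.exons):
                    oracle.extend(range(e.end - 1, e.start - 1, -1))
            else:
                oracle = [p for e in tx.exons for p in range(e.start, e.end)]
            for t in range(tx.length):
                blocks = tx.tx_to_genome(t, t + 1)
                assert len(blocks) == 1 and len(blocks[0]) == 1
                g = blocks[0].start
                assert g == oracle[t]
                assert tx.genome_to_tx(g) == t

    def test_block_lengths_sum(self, rng):
        for i in range(50):
            tx = random_transcript(rng, f"s{i}")
            a = int(rng.integers(0, tx.length))
            b = int(rng.integers(a + 1, tx.length + 1))
            blocks = tx.tx_to_genome(a, b)
            assert sum(len(x) for x in blocks) == b - a
            assert blocks == sorted(blocks, key=lambda x: x.start)


class TestPsiteAssignment:
    @pytest.fixture
    def ann(self):
        tx = TranscriptModel(
            "t1", "g1", "+", [GenomeInterval("chr1", 900, 1100)], "lncRNA"
        )
        txm = TranscriptModel(
            "t2", "g2", "-", [GenomeInterval("chr1", 900, 1100, "-")], "lncRNA"
        )
        return AnnotationSet([tx, txm])

    def test_plus_offset_convention(self, ann):
        reads = [FootprintRead("chr1", 1000, 1029, "+", 29, "A")]
        tracks, summ = assign_psites(reads, ann, PsiteOffsetTable({29: 12}))
        assert summ["assigned"] == 1
        # genomic P-site 1012 -> transcript position 112
        assert tracks[0].get("t1", 112) == 1

    def test_minus_offset_convention(self, ann):
        reads = [FootprintRead("chr1", 1000, 1029, "-", 29, "A")]
        tracks, _ = assign_psites(reads, ann, PsiteOffsetTable({29: 12}))
        # 5' end 1028, P-site 1016; minus transcript position = 1099 - 1016
        assert tracks[0].get("t2", 1099 - 1016) == 1

    def test_unknown_length_skip(self, ann):
        reads = [FootprintRead("chr1", 1000, 1017, "+", 17, "A")]
        tracks, summ = assign_psites(reads, ann, PsiteOffsetTable())
        assert summ["skipped_length"] == 1
        assert not tracks

    def test_conservation_of_reads(self, ann, rng):
        reads = []
        for i in range(500):
            start = int(rng.integers(800, 1200))
            length = int(rng.integers(24, 35))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(
                FootprintRead("chr1", start, start + length, strand, length, "A")
            )
        tracks, summ = assign_psites(reads, ann, PsiteOffsetTable())
        total_counts = sum(t.total() for t in tracks)
        assert (
            summ["assigned"] + summ["unassigned"] + summ["skipped_length"]
            == summ["total"]
            == 500
        )
        assert total_counts == summ["assigned"]

    def test_offset_table_validation(self):
        with pytest.raises(ValueError):
            PsiteOffsetTable({20: 25})

    def test_psite_table_roundtrip(self, tmp_path):
        tr = PsiteTrack("S1")
        tr.add("t1", 5, 3)
        tr.add("t1", 9)
        p = tmp_path / "ps.tsv"
        write_psite_table([tr], p)
        back = read_psite_table(p)
        assert back[0].counts == tr.counts


class TestBed12:
    class Rec:
        def __init__(self, orf_id, blocks, score=0.5):
            self.orf_id = orf_id
            self.genomic_blocks = blocks
            self.score = score

    def test_two_block_fields(self, tmp_path):
        rec = self.Rec(
            "o1",
            [GenomeInterval("chr1", 105, 110), GenomeInterval("chr1", 120, 125)],
        )
        p = tmp_path / "a.bed"
        write_bed12([rec], p)
        f = p.read_text().strip().split("\t")
        assert f[0:3] == ["chr1", "105", "125"]
        assert f[9] == "2"
        assert f[10] == "5,5"
        assert f[11] == "0,15"
        assert f[4] == "500"

    def test_single_block(self, tmp_path):
        rec = self.Rec("o1", [GenomeInterval("chr1", 10, 40)], score=2.0)
        p = tmp_path / "a.bed"
        write_bed12([rec], p)
        f = p.read_text().strip().split("\t")
        assert f[9] == "1" and f[11] == "0"
        assert f[4] == "1000"  # clamped

    def test_roundtrip(self, tmp_path):
        blocks = [GenomeInterval("chr2", 7, 19, "-"), GenomeInterval("chr2", 30, 36, "-")]
        p = tmp_path / "a.bed"
        write_bed12([self.Rec("o2", blocks)], p)
        back = read_bed12(p)
        assert back[0]["orf_id"] == "o2"
        assert back[0]["blocks"] == blocks

    def test_multi_chrom_error(self, tmp_path):
        rec = self.Rec(
            "o1", [GenomeInterval("chr1", 0, 5), GenomeInterval("chr2", 0, 5)]
        )
        with pytest.raises(ValueError):
            write_bed12([rec], tmp_path / "a.bed")
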