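import pytest

from junctiondb.rmats_io import EventType, Interval, SpliceEvent
from junctiondb.sequence_retrieval import (
    UNANNOTATED,
    AnnotationIndex,
    CoordinateError,
    FrameAnnotation,
    GeneNotFoundError,
    GenomeResource,
    annotate_frame,
    build_slices,
)
from junctiondb.utils import revcomp, wrap_fasta

UP = "ATGGCA"
ALT = "GTT"
DOWN = "TAAGGCTTA"
INTRON1 = "gtaagt"
INTRON2 = "ttacag"
CONTIG = UP + INTRON1 + ALT + INTRON2 + DOWN  # layout: 0..6 | 6..12 | 12..15 | 15..21 | 21..30


def se_event(strand="+", chrom="toy"):
    return SpliceEvent(
        event_id="SE_1",
        event_type=EventType.SE,
        gene_id="G1",
        gene_symbol="GENE",
        chromosome=chrom,
        strand=strand,
        anchor_exons=(Interval(0, 6), Interval(21, 30)),
        alt_exons=(Interval(12, 15),),
    )


@pytest.fixture(scope="module")
def genome(tmp_path_factory):
    d = tmp_path_factory.mktemp("genome")
    path = d / "toy.fa"
    mirrored = revcomp(CONTIG)
    path.write_text(f">toy\n{wrap_fasta(CONTIG)}\n>toy_rc\n{wrap_fasta(mirrored)}\n")
    return GenomeResource(path)


class TestBuildSlices:
    def test_plus_strand_concatenation(self, genome):
        included, excluded = build_slices(se_event(), genome)
        assert included.sequence == (UP + ALT + DOWN).upper()
        assert excluded.sequence == (UP + DOWN).upper()

    def test_minus_strand_is_revcomp_of_plus(self, genome):
        plus_inc, plus_exc = build_slices(se_event(), genome)
        n = len(CONTIG)
        mirror = SpliceEvent(
            event_id="SE_1",
            event_type=EventType.SE,
            gene_id="G1",
            gene_symbol="GENE",
            chromosome="toy_rc",
            strand="-",
            anchor_exons=(Interval(n - 30, n - 21), Interval(n - 6, n)),
            alt_exons=(Interval(n - 15, n - 12),),
        )
        minus_inc, minus_exc = build_slices(mirror, genome)
        assert minus_inc.sequence == plus_inc.sequence
        assert minus_exc.sequence == plus_exc.sequence

    def test_ri_length_bookkeeping(self, genome):
        event = SpliceEvent(
            event_id="RI_1",
            event_type=EventType.RI,
            gene_id="G1",
            gene_symbol="GENE",
            chromosome="toy",
            strand="+",
            anchor_exons=(Interval(0, 6), Interval(12, 15)),
            alt_exons=(Interval(6, 12),),
        )
        included, excluded = build_slices(event, genome)
        assert len(included.sequence) == len(excluded.sequence) + 6
        # retained intron yields one contiguous block
        assert included.block_structure == (Interval(0, 15),)

    def test_length_exactness(self, genome):
        for s in build_slices(se_event(), genome):
            assert len(s.sequence) == sum(b.length for b in s.block_structure)

    def test_contig_absent(self, genome):
        with pytest.raises(CoordinateError, match="contig"):
            build_slices(se_event(chrom="chrMissing"), genome)

    def test_interval_beyond_contig(self, genome):
        event = SpliceEvent(
            event_id="SE_2",
            event_type=EventType.SE,
            gene_id="G1",
            gene_symbol="GENE",
            chromosome="toy",
            strand="+",
            anchor_exons=(Interval(0, 6), Interval(21, 500)),
            alt_exons=(Interval(12, 15),),
        )
        with pytest.raises(CoordinateError):
            build_slices(event, genome)

    def test_trimming_respects_coding_bounds(self, genome):
        frame = FrameAnnotation("T1", 0, 2, 27, annotated=True)
        included, _ = build_slices(se_event(), genome, frame)
        assert included.block_structure[0].start == 2
        assert included.block_structure[-1].end == 27


GTF_TWO_TRANSCRIPTS = """\
chr1\ttoy\tgene\t1\t400\t.\t+\t.\tgene_id "G1"; gene_name "GENE";
chr1\ttoy\ttranscript\t1\t400\t.\t+\t.\tgene_id "G1"; transcript_id "TA";
chr1\ttoy\texon\t1\t100\t.\t+\t.\tgene_id "G1"; transcript_id "TA";
chr1\ttoy\tCDS\t11\t100\t.\t+\t0\tgene_id "G1"; transcript_id "TA";
chr1\ttoy\tCDS\t151\t200\t.\t+\t2\tgene_id "G1"; transcript_id "TA";
chr1\ttoy\ttranscript\t1\t400\t.\t+\t.\tgene_id "G1"; transcript_id "TB";
chr1\ttoy\tCDS\t21\t100\t.\t+\t1\tgene_id "G1"; transcript_id "TB";
chr1\ttoy\ttranscript\t1\t400\t.\t+\t.\tgene_id "G2"; transcript_id "TC";
chr1\ttoy\tgene\t500\t600\t.\t+\t.\tgene_id "G3"; gene_name "UTRGENE";
chr1\ttoy\ttranscript\t500\t600\t.\t+\t.\tgene_id "G3"; transcript_id "TD";
chr1\ttoy\tCDS\t561\t600\t.\t+\t0\tgene_id "G3"; transcript_id "TD";
"""


@pytest.fixture(scope="module")
def annotation(tmp_path_factory):
    d = tmp_path_factory.mktemp("gtf")
    path = d / "toy.gtf"
    path.write_text(GTF_TWO_TRANSCRIPTS)
    return AnnotationIndex(path)


def anchored_event(gene_id, anchor, strand="+", symbol="GENE"):
    return SpliceEvent(
        event_id="SE_9",
        event_type=EventType.SE,
        gene_id=gene_id,
        gene_symbol=symbol,
        chromosome="chr1",
        strand=strand,
        anchor_exons=(anchor, Interval(700, 720)),
        alt_exons=(Interval(650, 680),),
    )


class TestAnnotateFrame:
    def test_single_transcript_phase(self, annotation):
        frame = annotate_frame(anchored_event("G1", Interval(10, 100)), annotation)
        assert frame.annotated and frame.phase == 0
        # TA has the longer total CDS, so it beats TB
        assert frame.transcript_id == "TA"
        assert frame.coding_start == 10 and frame.coding_end == 200

    def test_longest_cds_wins(self, annotation):
        # both TA (phase 0 at 11-100) and TB (phase 1 at 21-100) overlap here
        frame = annotate_frame(anchored_event("G1", Interval(30, 90)), annotation)
        assert frame.transcript_id == "TA" and frame.phase == 0

    def test_utr_anchor_unannotated(self, annotation):
        frame = annotate_frame(anchored_event("G3", Interval(500, 550)), annotation)
        assert frame == UNANNOTATED

    def test_gene_absent_raises(self, annotation):
        with pytest.raises(GeneNotFoundError):
            annotate_frame(
                anchored_event("G999", Interval(10, 100), symbol="NOSUCH"), annotation
            )

    def test_gene_resolved_by_symbol_fallback(self, annotation):
        frame = annotate_frame(
            anchored_event("G999", Interval(10, 100), symbol="GENE"), annotation
        )
        assert frame.annotated and frame.transcript_id == "TA"

    def test_minus_strand_feature_mismatch(self, annotation):
        frame = annotate_frame(
            anchored_event("G1", Interval(10, 100), strand="-"), annotation
        )
        assert not frame.annotated


class TestFixtureBundleProperties:
    def test_annotated_slices_stay_inside_coding_bounds(self, default_bundle):
        from junctiondb.rmats_io import parse_rmats_table, rmats_filename

        genome = GenomeResource(default_bundle.genome_path)
        annotation = AnnotationIndex(default_bundle.gtf_path)
        checked = 0
        for etype in EventType:
            records = parse_rmats_table(
                default_bundle.rmats_dir / rmats_filename(etype), etype
            )
            for event, _ in records:
                frame = annotate_frame(event, annotation)
                if not frame.annotated:
                    continue
                for s in build_slices(event, genome, frame):
                    assert s.block_structure[0].start >= frame.coding_start
                    assert s.block_structure[-1].end <= frame.coding_end
                    checked += 1
        assert checked > 10
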