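import numpy as np
import pytest

from junctiondb.rmats_io import EventType, Interval, SpliceEvent
from junctiondb.stitching_db import (
    CanonicalRecord,
    IsoformEntry,
    OrphanVerdict,
    deduplicate,
    load_canonical_fasta,
    read_database,
    stitch,
    write_database,
)
from junctiondb.translation import TranslatedSlice


def make_event(event_id="SE_1", etype=EventType.SE):
    return SpliceEvent(
        event_id=event_id,
        event_type=etype,
        gene_id="G1",
        gene_symbol="GENE",
        chromosome="chr1",
        strand="+",
        anchor_exons=(Interval(100, 200), Interval(400, 500)),
        alt_exons=(Interval(250, 310),),
    )


def make_tslice(aa):
    return TranslatedSlice(
        aa_sequence=aa, frame_used=0, used_annotated_frame=True, ptc_found=False
    )


def unique_canonical(seed=0, length=60):
    """Random canonical sequence; all its 10-mers are unique (checked)."""
    rng = np.random.default_rng(seed)
    while True:
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), length))
        kmers = [seq[i : i + 10] for i in range(length - 9)]
        if len(set(kmers)) == len(kmers):
            return CanonicalRecord("P00001", "GENE", seq, "sp|P00001|GENE_TEST")


class TestStitch:
    def test_string_surgery_oracle(self):
        canonical = unique_canonical()
        c = canonical.aa_sequence
        slice_aa = list(c[5:35])
        for pos in (18, 19, 20):  # interior: between the two overhang words
            slice_aa[pos - 5] = "W" if c[pos] != "W" else "Y"
        slice_aa = "".join(slice_aa)
        expected = c[:5] + slice_aa + c[35:]  # independent surgery
        entry = stitch(make_tslice(slice_aa), canonical, event=make_event(), which="included", tier=1)
        assert isinstance(entry, IsoformEntry)
        assert entry.aa_sequence == expected
        assert len(entry.aa_sequence) == len(c)
        assert entry.slice_region == (5, 35)
        assert not entry.is_canonical_duplicate

    def test_identity_stitch_flags_duplicate(self):
        canonical = unique_canonical(1)
        slice_aa = canonical.aa_sequence[10:40]
        entry = stitch(make_tslice(slice_aa), canonical, event=make_event(), which="included", tier=1)
        assert isinstance(entry, IsoformEntry)
        assert entry.aa_sequence == canonical.aa_sequence
        assert entry.is_canonical_duplicate

    def test_unmatched_n_overhang_is_orphan(self):
        canonical = unique_canonical(2)
        slice_aa = "W" * 10 + canonical.aa_sequence[30:45]
        verdict = stitch(make_tslice(slice_aa), canonical, event=make_event(), which="included", tier=1)
        assert isinstance(verdict, OrphanVerdict)
        assert verdict.reason == "n_overhang_unmatched"

    def test_unmatched_c_overhang_is_orphan(self):
        canonical = unique_canonical(3)
        slice_aa = canonical.aa_sequence[5:20] + "W" * 10
        verdict = stitch(make_tslice(slice_aa), canonical, event=make_event(), which="excluded", tier=1)
        assert isinstance(verdict, OrphanVerdict)
        assert verdict.reason == "c_overhang_unmatched"

    def test_short_slice_is_orphan(self):
        canonical = unique_canonical(4)
        verdict = stitch(
            make_tslice(canonical.aa_sequence[:19]), canonical,
            event=make_event(), which="included", tier=4,
        )
        assert isinstance(verdict, OrphanVerdict) and verdict.reason == "too_short"

    def test_c_match_must_follow_n_match(self):
        # C-terminal word occurs only before the N-terminal word: orphan
        c = "QWERTYASDFG" + "HIKLMNPACDE" + "QWERTYASDFG"[::-1]
        canonical = CanonicalRecord("P1", "GENE", "NMWYACDEFGHIKL" + c, "h")
        slice_aa = c[11:22] + "NMWYACDEFG"  # C 10-mer sits before the N match
        verdict = stitch(make_tslice(slice_aa), canonical, event=make_event(), which="included", tier=1)
        assert isinstance(verdict, OrphanVerdict)

    def test_reconstruction_invariant(self):
        canonical = unique_canonical(5)
        c = canonical.aa_sequence
        slice_aa = c[8:18] + "WWW" + c[30:40]
        entry = stitch(make_tslice(slice_aa), canonical, event=make_event(), which="included", tier=1)
        a, b = entry.slice_region
        cs = c.find(slice_aa[-10:], a + 1)
        assert entry.aa_sequence[:a] + c[a : cs + 10] + entry.aa_sequence[b:] == c


class TestDeduplicate:
    def entry(self, aa, event_id="SE_1", tier=1, dup=False):
        return IsoformEntry(
            aa_sequence=aa,
            gene_symbol="GENE",
            canonical_accession="P00001",
            event_ids=(event_id,),
            event_type=EventType.SE,
            tier=tier,
            slice_region=(0, len(aa)),
            genomic_tag="chr1:1-2:+",
            is_canonical_duplicate=dup,
        )

    def test_duplicate_collapse_merges_provenance(self):
        merged = deduplicate(
            [self.entry("PEPTIDEAAA", "SE_1"), self.entry("PEPTIDEAAA", "SE_2")], []
        )
        assert len(merged) == 1
        assert merged[0].event_ids == ("SE_1", "SE_2")

    def test_lowest_tier_retained(self):
        merged = deduplicate(
            [self.entry("PEPTIDEAAA", "SE_1", tier=4), self.entry("PEPTIDEAAA", "SE_2", tier=2)],
            [],
        )
        assert merged[0].tier == 2

    def test_canonical_identical_flagged(self):
        canonical = CanonicalRecord("P00001", "GENE", "PEPTIDEAAA", "h")
        merged = deduplicate([self.entry("PEPTIDEAAA")], [canonical])
        assert merged[0].is_canonical_duplicate

    def test_distinct_sequences_kept(self):
        merged = deduplicate([self.entry("PEPTIDEAAA"), self.entry("PEPTIDECCC", "SE_3")], [])
        assert len(merged) == 2


class TestWriteDatabase:
    def make_entries(self, n=3):
        rng = np.random.default_rng(0)
        out = []
        for i in range(n):
            aa = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 70))
            out.append(
                IsoformEntry(
                    aa_sequence=aa,
                    gene_symbol="GENE",
                    canonical_accession="P00001",
                    event_ids=(f"SE_{i}",),
                    event_type=EventType.SE,
                    tier=1 + i % 4,
                    slice_region=(0, 70),
                    genomic_tag=f"chr1:{100 + i}-{200 + i}:+",
                )
            )
        return out

    def test_roundtrip_and_decoys(self, tmp_path):
        entries = self.make_entries()
        paths = write_database(entries, [], tmp_path / "db.fasta", include_decoys=True)
        targets = read_database(paths[0])
        assert len(targets) == 3
        for rec, entry in zip(targets, entries):
            assert rec["aa_sequence"] == entry.aa_sequence
            assert rec["gene_symbol"] == "GENE"
            assert rec["tier"] == entry.tier
            assert rec["strand"] == "+"
        decoy_text = paths[1].read_text()
        assert decoy_text.count(">DECOY_") == 3
        # decoy reversal is a length-preserving involution
        from Bio import SeqIO

        for target, decoy in zip(SeqIO.parse(str(paths[0]), "fasta"), SeqIO.parse(str(paths[1]), "fasta")):
            assert str(decoy.seq) == str(target.seq)[::-1]
            assert str(decoy.seq)[::-1] == str(target.seq)
            assert len(decoy.seq) == len(target.seq)

    def test_header_grammar(self, tmp_path):
        entries = self.make_entries(1)
        write_database(entries, [], tmp_path / "db.fasta")
        header = (tmp_path / "db.fasta").read_text().splitlines()[0]
        assert header == ">sp|P00001-SE1|GENE_1 chr1:100-200:+"

    def test_empty_database(self, tmp_path):
        paths = write_database([], [], tmp_path / "db.fasta", include_decoys=True)
        assert paths[0].read_text() == ""
        assert read_database(paths[0]) == []

    def test_no_stop_or_invalid_chars_emitted(self, default_run):
        _, out = default_run
        for rec in read_database(out / "database.fasta"):
            assert set(rec["aa_sequence"]) <= set("ACDEFGHIKLMNPQRSTVWYX")


class TestLoadCanonical:
    def test_uniprot_headers(self, tmp_path):
        path = tmp_path / "prot.fasta"
        path.write_text(
            ">sp|P12345|NAME_HUMAN Some protein OS=Homo sapiens GN=MYGENE PE=1\n"
            "MKTAYIAKQR\n"
            ">plainheader\nMSEQWENCE\n"
        )
        records = load_canonical_fasta(path)
        assert records[0].accession == "P12345"
        assert records[0].gene_symbol == "MYGENE"
        assert records[0].aa_sequence == "MKTAYIAKQR"
        assert records[1].accession == "plainheader"
        assert records[1].gene_symbol == "plainheader"
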