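"""Genome slice extraction and annotated reading-frame recovery.

Each splice event resolves to two nucleotide slices (included / excluded
junction alternative), strand-corrected to transcript orientation. The
translation frame is recovered from the GTF CDS record overlapping the
transcript-5' anchor exon; when a matched annotation provides coding
bounds, slice ends are trimmed so nothing outside the coding region is
translated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import gffutils
from pyfaidx import Fasta

from .rmats_io import EventType, Interval, SpliceEvent
from .utils import revcomp

__all__ = [
    "GenomeResource",
    "FrameAnnotation",
    "NucleotideSlice",
    "AnnotationIndex",
    "GeneNotFoundError",
    "CoordinateError",
    "SliceQualityError",
    "build_slices",
    "annotate_frame",
]

_VALID_BASES = set("ACGTN")
MAX_N_FRACTION = 0.30


class GeneNotFoundError(LookupError):
    pass


class CoordinateError(ValueError):
    pass


class SliceQualityError(ValueError):
    """Slice exceeds the tolerated fraction of ambiguous bases."""


class GenomeResource:
    """Random access to an (indexed) genome FASTA, uppercased on fetch."""

    def __init__(self, fasta_path: str | Path):
        self.fasta_path = Path(fasta_path)
        self._fasta = Fasta(str(fasta_path), sequence_always_upper=True)

    @property
    def contig_names(self) -> list[str]:
        return list(self._fasta.keys())

    def contig_length(self, contig: str) -> int:
        if contig not in self._fasta:
            raise CoordinateError(f"contig {contig!r} not in genome")
        return len(self._fasta[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Plus-strand sequence for 0-based half-open [start, end)."""
        if contig not in self._fasta:
            raise CoordinateError(f"contig {contig!r} not in genome")
        if start < 0 or end > len(self._fasta[contig]) or end <= start:
            raise CoordinateError(
                f"interval [{start}, {end}) outside contig {contig} "
                f"(length {len(self._fasta[contig])})"
            )
        seq = str(self._fasta[contig][start:end])
        if len(seq) != end - start:
            raise CoordinateError(f"retrieved {len(seq)} nt for a {end - start} nt interval")
        return seq

    def close(self) -> None:
        self._fasta.close()


@dataclass(frozen=True)
class FrameAnnotation:
    transcript_id: Optional[str]
    phase: Optional[int]  # bases to skip before the first complete codon
    coding_start: Optional[int]  # genomic, 0-based
    coding_end: Optional[int]  # genomic, half-open
    annotated: bool

    def __post_init__(self) -> None:
        if self.annotated:
            if self.phase not in (0, 1, 2):
                raise ValueError("annotated frame requires phase in {0,1,2}")
            if self.coding_start is not None and self.coding_end is not None:
                if self.coding_start > self.coding_end:
                    raise ValueError("coding_start > coding_end")


UNANNOTATED = FrameAnnotation(None, None, None, None, annotated=False)


@dataclass(frozen=True)
class NucleotideSlice:
    event_id: str
    which: str  # "included" | "excluded"
    sequence: str  # 5'->3' in transcript orientation
    block_structure: tuple[Interval, ...]  # genomic order, post-trimming
    frame_hint: FrameAnnotation = UNANNOTATED

    def __post_init__(self) -> None:
        if self.which not in ("included", "excluded"):
            raise ValueError(f"bad slice kind {self.which!r}")
        if set(self.sequence) - _VALID_BASES:
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise ValueError(f"non-ACGTN characters in slice: {bad}")
        if len(self.sequence) != sum(b.length for b in self.block_structure):
            raise ValueError("sequence length != sum of block lengths")


def _event_blocks(event: SpliceEvent) -> tuple[list[Interval], list[Interval]]:
    """Genomic-order blocks for the (included, excluded) slices."""
    left, right = event.anchor_exons
    if event.event_type is EventType.MXE:
        alt_lo, alt_hi = event.alt_exons
        included = sorted([left, alt_lo, right], key=lambda b: b.start)
        excluded = sorted([left, alt_hi, right], key=lambda b: b.start)
    else:
        included = sorted([left, *event.alt_exons, right], key=lambda b: b.start)
        excluded = [left, right]
    return included, excluded


def _trim_blocks(blocks: list[Interval], frame: FrameAnnotation) -> list[Interval]:
    """Clip the genomic-leftmost start and rightmost end to the coding span."""
    if not frame.annotated or frame.coding_start is None or frame.coding_end is None:
        return blocks
    trimmed: list[Interval] = []
    for i, b in enumerate(blocks):
        start, end = b.start, b.end
        if i == 0:
            start = max(start, frame.coding_start)
        if i == len(blocks) - 1:
            end = min(end, frame.coding_end)
        if end <= start:
            raise CoordinateError(
                f"block [{b.start},{b.end}) trimmed away by coding span "
                f"[{frame.coding_start},{frame.coding_end})"
            )
        trimmed.append(Interval(start, end))
    return trimmed


def _merge_adjacent(blocks: list[Interval]) -> list[Interval]:
    merged = [blocks[0]]
    for b in blocks[1:]:
        if b.start == merged[-1].end:
            merged[-1] = Interval(merged[-1].start, b.end)
        elif b.start < merged[-1].end:
            raise CoordinateError("overlapping slice blocks")
        else:
            merged.append(b)
    return merged


def _assemble(
    event: SpliceEvent,
    genome: GenomeResource,
    blocks: list[Interval],
    which: str,
    frame: FrameAnnotation,
) -> NucleotideSlice:
    blocks = _merge_adjacent(_trim_blocks(blocks, frame))
    seq = "".join(genome.fetch(event.chromosome, b.start, b.end) for b in blocks)
    if event.strand == "-":
        seq = revcomp(seq)
    if seq.count("N") > MAX_N_FRACTION * len(seq):
        raise SliceQualityError(
            f"{event.event_id}/{which}: more than {MAX_N_FRACTION:.0%} ambiguous bases"
        )
    return NucleotideSlice(
        event_id=event.event_id,
        which=which,
        sequence=seq,
        block_structure=tuple(blocks),
        frame_hint=frame,
    )


def build_slices(
    event: SpliceEvent,
    genome: GenomeResource,
    frame: FrameAnnotation = UNANNOTATED,
) -> tuple[NucleotideSlice, NucleotideSlice]:
    """Extract the (included, excluded) nucleotide slices for an event.

    Minus-strand slices are reverse-complemented so the sequence reads
    5'->3' of the mRNA; block_structure stays in genomic order.
    """
    inc_blocks, exc_blocks = _event_blocks(event)
    included = _assemble(event, genome, inc_blocks, "included", frame)
    excluded = _assemble(event, genome, exc_blocks, "excluded", frame)
    return included, excluded


class AnnotationIndex:
    """CDS/transcript lookup built once from an Ensembl-dialect GTF."""

    def __init__(self, gtf_path: str | Path):
        self.gtf_path = Path(gtf_path)
        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        # gene_id -> transcript_id -> list of CDS feature tuples
        self._cds: dict[str, dict[str, list[gffutils.Feature]]] = {}
        self._canonical_tag: dict[str, bool] = {}
        self._symbol_to_gene: dict[str, str] = {}
        for feat in db.features_of_type("CDS"):
            gene_id = feat.attributes.get("gene_id", ["?"])[0]
            tx_id = feat.attributes.get("transcript_id", ["?"])[0]
            self._cds.setdefault(gene_id, {}).setdefault(tx_id, []).append(feat)
            tags = feat.attributes.get("tag", [])
            if "Ensembl_canonical" in tags:
                self._canonical_tag[tx_id] = True
        for feat in db.features_of_type("gene"):
            gene_id = feat.attributes.get("gene_id", ["?"])[0]
            name = feat.attributes.get("gene_name", [""])[0]
            if name:
                self._symbol_to_gene.setdefault(name, gene_id)
        for feat in db.features_of_type("transcript"):
            tx_id = feat.attributes.get("transcript_id", ["?"])[0]
            if "Ensembl_canonical" in feat.attributes.get("tag", []):
                self._canonical_tag[tx_id] = True
        self._gene_ids = set(self._cds) | {
            f.attributes.get("gene_id", ["?"])[0] for f in db.features_of_type("gene")
        }

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self._gene_ids

    def resolve_gene(self, gene_id: str, gene_symbol: str = "") -> str:
        if gene_id in self._gene_ids:
            return gene_id
        if gene_symbol and gene_symbol in self._symbol_to_gene:
            return self._symbol_to_gene[gene_symbol]
        raise GeneNotFoundError(f"gene {gene_id!r} not in annotation")

    def transcripts_with_cds(self, gene_id: str) -> dict[str, list[gffutils.Feature]]:
        return self._cds.get(gene_id, {})

    def is_canonical(self, transcript_id: str) -> bool:
        return self._canonical_tag.get(transcript_id, False)


def annotate_frame(event: SpliceEvent, annotation: AnnotationIndex) -> FrameAnnotation:
    """Recover the annotated phase at the transcript-5' anchor exon.

    A transcript qualifies when one of its CDS records overlaps the
    upstream (5') anchor exon. Preference: canonical-tagged transcript,
    then longest total CDS, then lexicographically smallest transcript id.
    Returns an unannotated frame when no transcript qualifies.
    """
    gene_id = annotation.resolve_gene(event.gene_id, event.gene_symbol)
    anchor = event.upstream_anchor
    candidates: list[tuple[int, int, str, FrameAnnotation]] = []
    for tx_id, cds_feats in annotation.transcripts_with_cds(gene_id).items():
        overlapping = [
            f
            for f in cds_feats
            if f.seqid == event.chromosome
            and f.strand == event.strand
            and Interval(f.start - 1, f.end).overlaps(anchor)
        ]
        if not overlapping:
            continue
        # the CDS piece at the anchor whose 5' end is most upstream in
        # transcript orientation (the phase applies at that 5' end)
        if event.strand == "+":
            piece = min(overlapping, key=lambda f: f.start)
        else:
            piece = max(overlapping, key=lambda f: f.end)
        total_cds = sum(f.end - f.start + 1 for f in cds_feats)
        coding_start = min(f.start - 1 for f in cds_feats)
        coding_end = max(f.end for f in cds_feats)
        frame = FrameAnnotation(
            transcript_id=tx_id,
            phase=int(piece.frame),
            coding_start=coding_start,
            coding_end=coding_end,
            annotated=True,
        )
        canonical_rank = 0 if annotation.is_canonical(tx_id) else 1
        candidates.append((canonical_rank, -total_cds, tx_id, frame))
    if not candidates:
        return UNANNOTATED
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    return candidates[0][3]
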