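"""Self-consistent toy input bundles with planted ground truth.

Generates a genome FASTA, an Ensembl-dialect GTF, a canonical proteome
FASTA and the five rMATS JC tables, all describing the same synthetic
loci. Each locus plants one AS event whose filter verdict, translation
tier and stitched product are known by construction: protein fragments
are drawn first and back-translated to nucleotides, so the expected
novel sequence is assembled by direct string surgery on the canonical
protein rather than by running the pipeline.

Template catalogue (cycled by :func:`generate_fixture`):

======  ======  ====  ========================================
name    type    tier  what it exercises
======  ======  ====  ========================================
se1     SE      1     frame-preserving cassette deletion (+)
se1m    SE      1     same construction on the minus strand
mxe1    MXE     1     mutually exclusive exon substitution
a3ss1   A3SS    1     acceptor-extension insertion
a5ss1   A5SS    1     donor-extension insertion
ri1     RI      1     retained-intron insertion
se2     SE      2     frameshifting cassette, PTC-free pair
se3     SE      3     unannotated anchor, alternative frame
se4     SE      4     cassette carrying an in-frame stop
se1low  SE      1     low-expression event (filtered out)
se1inc  SE      1     replicate-inconsistent event (p=0.005)
se1dup  SE      1     two rMATS rows for one junction
se1noc  SE      1     gene absent from the canonical proteome
se1ph   SE      1     nonzero annotated phase at the anchor
======  ======  ====  ========================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .rmats_io import EventType, Interval, ReplicateCounts, SpliceEvent
from .translation import CODON_TABLE, STOP_CODONS
from .utils import revcomp, wrap_fasta

__all__ = [
    "FixtureConfig",
    "FixtureBundle",
    "ToyLocus",
    "GenerationError",
    "TEMPLATE_NAMES",
    "generate_fixture",
    "mybpc3_worked_example",
    "write_rmats_tables",
    "read_manifest",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TABLE.items()):
    if aa != "*":
        _CODONS_FOR.setdefault(aa, []).append(codon)

# kills reading frames 1 and 2 (early stop) while staying clean in frame 0
_FRAME_TRAP = "TTAATTAAC"  # frame 0: L I N ; frame 1: ..TAA ; frame 2: ..TAA

TEMPLATE_NAMES = [
    "se1", "se1m", "mxe1", "a3ss1", "a5ss1", "ri1",
    "se2", "se3", "se4",
    "se1low", "se1inc", "se1dup", "se1noc", "se1ph",
]


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureConfig:
    lambda_low: float = 1.0
    lambda_high: float = 60.0
    replicates_per_sample: int = 1  # two sample columns -> 2x this many
    manifest_theta: int = 4  # theta used for the manifest's verdicts
    p_cutoff: float = 0.01
    pad: int = 50
    ri_tier2_intron_nt: Optional[int] = None  # opt-in frameshifting RI template

    def __post_init__(self) -> None:
        if self.ri_tier2_intron_nt is not None and self.ri_tier2_intron_nt % 3 == 0:
            raise GenerationError(
                "ri_tier2 requires an intron length not divisible by 3 "
                f"(got {self.ri_tier2_intron_nt}); it would not frameshift"
            )


@dataclass
class _Segment:
    name: str
    seq: str
    role: str  # exon | utr_exon | intron | extra


@dataclass
class _Plan:
    """Forward-orientation locus layout before genome placement."""

    template: str
    segments: list[_Segment]
    event_type: EventType
    anchor_names: tuple[str, str]  # transcript order (5' anchor, 3' anchor)
    alt_names: tuple[str, ...]
    canonical_protein: str
    tier: int
    included_fate: str
    excluded_fate: str
    novel_protein: Optional[str]
    count_class: str = "high"
    p_value: Optional[float] = None
    n_rows: int = 1
    in_proteome: bool = True


@dataclass
class ToyLocus:
    index: int
    template: str
    contig: str
    gene_id: str
    transcript_id: str
    gene_symbol: str
    accession: str
    strand: str
    contig_seq: str
    exons: list[Interval]  # transcript order, genomic coords
    cds: list[tuple[Interval, int]]  # (interval, frame), transcript order
    canonical_protein: str
    in_proteome: bool
    plan: _Plan
    segment_coords: dict[str, Interval]


@dataclass
class FixtureBundle:
    out_dir: Path
    genome_path: Path
    gtf_path: Path
    proteome_path: Path
    rmats_dir: Path
    manifest_path: Path
    manifest: list[dict]
    loci: list[ToyLocus]


# ---------------------------------------------------------------------------
# sequence helpers


def _frag(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET)) for _ in range(n))


def _backtranslate(aa: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_CODONS_FOR[a]) for a in aa)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT")) for _ in range(n))


def _translate0(nt: str) -> tuple[str, bool]:
    """Frame-0 translation until stop; returns (aa, stopped_before_end)."""
    aas = []
    n_codons = len(nt) // 3
    for i in range(n_codons):
        codon = nt[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            return "".join(aas), i < n_codons - 1
        aas.append(CODON_TABLE[codon])
    return "".join(aas), False


# ---------------------------------------------------------------------------
# locus templates (all built in forward/transcript orientation)


def _three_exon_se(rng: np.random.Generator, template: str, **over) -> _Plan:
    u_aa = "M" + _frag(rng, 19)
    a_aa = _frag(rng, 10)
    d_aa = _frag(rng, 20)
    canonical = u_aa + a_aa + d_aa
    segments = [
        _Segment("E1", _backtranslate(u_aa, rng), "exon"),
        _Segment("i1", _random_dna(rng, 40), "intron"),
        _Segment("E2", _backtranslate(a_aa, rng), "exon"),
        _Segment("i2", _random_dna(rng, 40), "intron"),
        _Segment("E3", _backtranslate(d_aa, rng) + "TAA", "exon"),
    ]
    kwargs = dict(
        template=template,
        segments=segments,
        event_type=EventType.SE,
        anchor_names=("E1", "E3"),
        alt_names=("E2",),
        canonical_protein=canonical,
        tier=1,
        included_fate="canonical_dup",
        excluded_fate="novel",
        novel_protein=u_aa + d_aa,
    )
    kwargs.update(over)
    return _Plan(**kwargs)


def _plan_se1(rng, cfg):
    return _three_exon_se(rng, "se1")


def _plan_se1m(rng, cfg):
    return _three_exon_se(rng, "se1m")  # strand flip happens at placement


def _plan_se1low(rng, cfg):
    return _three_exon_se(rng, "se1low", count_class="low")


def _plan_se1inc(rng, cfg):
    return _three_exon_se(rng, "se1inc", p_value=0.005)


def _plan_se1dup(rng, cfg):
    return _three_exon_se(rng, "se1dup", n_rows=2)


def _plan_se1noc(rng, cfg):
    return _three_exon_se(
        rng,
        "se1noc",
        in_proteome=False,
        included_fate="orphan:no_canonical",
        excluded_fate="orphan:no_canonical",
        novel_protein=None,
    )


def _plan_mxe1(rng, cfg):
    u_aa = "M" + _frag(rng, 19)
    a1_aa = _frag(rng, 8)
    a2_aa = _frag(rng, 8)
    d_aa = _frag(rng, 20)
    canonical = u_aa + a1_aa + d_aa
    segments = [
        _Segment("E1", _backtranslate(u_aa, rng), "exon"),
        _Segment("i1", _random_dna(rng, 40), "intron"),
        _Segment("E2", _backtranslate(a1_aa, rng), "exon"),
        _Segment("i2", _random_dna(rng, 30), "intron"),
        _Segment("X", _backtranslate(a2_aa, rng), "extra"),
        _Segment("i3", _random_dna(rng, 30), "intron"),
        _Segment("E3", _backtranslate(d_aa, rng) + "TAA", "exon"),
    ]
    return _Plan(
        template="mxe1",
        segments=segments,
        event_type=EventType.MXE,
        anchor_names=("E1", "E3"),
        alt_names=("E2", "X"),
        canonical_protein=canonical,
        tier=1,
        included_fate="canonical_dup",
        excluded_fate="novel",
        novel_protein=u_aa + a2_aa + d_aa,
    )


def _two_exon_insertion(rng, template, etype, alt_adjacent_to):
    """A3SS / A5SS / RI: canonical skips a codon-aligned extra segment."""
    u_aa = "M" + _frag(rng, 19)
    x_aa = _frag(rng, 6)
    d_aa = _frag(rng, 20)
    canonical = u_aa + d_aa
    x_nt = _backtranslate(x_aa, rng)
    if etype is EventType.RI:
        segments = [
            _Segment("E1", _backtranslate(u_aa, rng), "exon"),
            _Segment("X", x_nt, "extra"),  # the entire intron, retained
            _Segment("E2", _backtranslate(d_aa, rng) + "TAA", "exon"),
        ]
    elif alt_adjacent_to == "down":  # A3SS: acceptor extends upstream
        segments = [
            _Segment("E1", _backtranslate(u_aa, rng), "exon"),
            _Segment("i1", _random_dna(rng, 40), "intron"),
            _Segment("X", x_nt, "extra"),
            _Segment("E2", _backtranslate(d_aa, rng) + "TAA", "exon"),
        ]
    else:  # A5SS: donor extends downstream of the upstream exon
        segments = [
            _Segment("E1", _backtranslate(u_aa, rng), "exon"),
            _Segment("X", x_nt, "extra"),
            _Segment("i1", _random_dna(rng, 40), "intron"),
            _Segment("E2", _backtranslate(d_aa, rng) + "TAA", "exon"),
        ]
    return _Plan(
        template=template,
        segments=segments,
        event_type=etype,
        anchor_names=("E1", "E2"),
        alt_names=("X",),
        canonical_protein=canonical,
        tier=1,
        included_fate="novel",
        excluded_fate="canonical_dup",
        novel_protein=u_aa + x_aa + d_aa,
    )


def _plan_a3ss1(rng, cfg):
    return _two_exon_insertion(rng, "a3ss1", EventType.A3SS, "down")


def _plan_a5ss1(rng, cfg):
    return _two_exon_insertion(rng, "a5ss1", EventType.A5SS, "up")


def _plan_ri1(rng, cfg):
    return _two_exon_insertion(rng, "ri1", EventType.RI, None)


def _plan_se2(rng, cfg):
    """Frameshifting 7 nt cassette; both slices PTC-free (tier 2)."""
    u_aa = "M" + _frag(rng, 19)
    d_aa = _frag(rng, 20)
    canonical = u_aa + d_aa
    u_nt = _backtranslate(u_aa, rng)
    for _ in range(300):
        a_nt = _random_dna(rng, 7)
        d_nt = _backtranslate(d_aa, rng)
        inc_coding = u_nt + a_nt + d_nt  # trimmed slice (stop removed by CDS bounds)
        aa, early_stop = _translate0(inc_coding)
        if early_stop:
            continue
        if aa[-10:] in canonical:  # the shifted tail must not re-stitch
            continue
        segments = [
            _Segment("E1", u_nt, "exon"),
            _Segment("i1", _random_dna(rng, 30), "intron"),
            _Segment("A", a_nt, "extra"),
            _Segment("i2", _random_dna(rng, 30), "intron"),
            _Segment("E2", d_nt + "TAA", "exon"),
        ]
        return _Plan(
            template="se2",
            segments=segments,
            event_type=EventType.SE,
            anchor_names=("E1", "E2"),
            alt_names=("A",),
            canonical_protein=canonical,
            tier=2,
            included_fate="orphan:c_overhang_unmatched",
            excluded_fate="canonical_dup",
            novel_protein=None,
        )
    raise GenerationError("se2: could not build a PTC-free frameshift cassette")


def _plan_se3(rng, cfg):
    """Anchor exon entirely 5' UTR -> no annotated frame -> tier 3.

    The UTR opens with a frame trap so only frame 0 is PTC-free, making
    the tier-3 frame choice unambiguous. Both slices begin with
    UTR-encoded residues and are therefore unstitchable orphans.
    """
    utr_nt = _FRAME_TRAP + _backtranslate(_frag(rng, 7), rng)  # 30 nt, frames 1/2 trapped
    m_aa = "M" + _frag(rng, 11)
    d_aa = _frag(rng, 20)
    canonical = m_aa + d_aa
    segments = [
        _Segment("E1", utr_nt, "utr_exon"),
        _Segment("i1", _random_dna(rng, 40), "intron"),
        _Segment("E2", _backtranslate(m_aa, rng), "exon"),
        _Segment("i2", _random_dna(rng, 40), "intron"),
        _Segment("E3", _backtranslate(d_aa, rng) + "TAA", "exon"),
    ]
    return _Plan(
        template="se3",
        segments=segments,
        event_type=EventType.SE,
        anchor_names=("E1", "E3"),
        alt_names=("E2",),
        canonical_protein=canonical,
        tier=3,
        included_fate="orphan:n_overhang_unmatched",
        excluded_fate="orphan:n_overhang_unmatched",
        novel_protein=None,
    )


def _plan_se4(rng, cfg):
    """Cassette with an internal in-frame stop -> tier 4.

    The upstream exon opens with the frame trap right after the start
    codon, so no alternative common frame can rescue the pair (tier 3 is
    ruled out) and the pair resolves as one-PTC tier 4.
    """
    u_aa = "M" + "LIN" + _frag(rng, 16)  # LIN is the frame trap in frame 0
    d_aa = _frag(rng, 20)
    canonical = u_aa + d_aa
    u_nt = "ATG" + _FRAME_TRAP + _backtranslate(u_aa[4:], rng)
    for _ in range(300):
        head = _backtranslate(_frag(rng, 2), rng)
        tail = _backtranslate(_frag(rng, 2), rng)
        a_nt = head + "TAA" + tail  # 15 nt, frame-preserving, PTC inside
        trunc_aa, _ = _translate0(u_nt + a_nt)
        if len(trunc_aa) >= 20 and trunc_aa[-10:] not in canonical:
            break
    else:
        raise GenerationError("se4: could not build the PTC cassette")
    segments = [
        _Segment("E1", u_nt, "exon"),
        _Segment("i1", _random_dna(rng, 30), "intron"),
        _Segment("A", a_nt, "extra"),
        _Segment("i2", _random_dna(rng, 30), "intron"),
        _Segment("E2", _backtranslate(d_aa, rng) + "TAA", "exon"),
    ]
    return _Plan(
        template="se4",
        segments=segments,
        event_type=EventType.SE,
        anchor_names=("E1", "E2"),
        alt_names=("A",),
        canonical_protein=canonical,
        tier=4,
        included_fate="orphan:c_overhang_unmatched",
        excluded_fate="canonical_dup",
        novel_protein=None,
    )


def _plan_se1ph(rng, cfg):
    """Upstream anchor exon starting mid-codon (annotated phase 2)."""
    f0_aa = "M" + _frag(rng, 6)
    f1_aa = _frag(rng, 20)
    fa_aa = _frag(rng, 10)
    f2_aa = _frag(rng, 20)
    canonical = f0_aa + f1_aa + fa_aa + f2_aa
    nt = _backtranslate(canonical, rng) + "TAA"
    b0 = 3 * len(f0_aa) + 1  # mid-codon exon boundary
    b1 = 3 * (len(f0_aa) + len(f1_aa))
    b2 = b1 + 3 * len(fa_aa)
    segments = [
        _Segment("E0", nt[:b0], "exon"),
        _Segment("i0", _random_dna(rng, 30), "intron"),
        _Segment("E1", nt[b0:b1], "exon"),
        _Segment("i1", _random_dna(rng, 30), "intron"),
        _Segment("E2", nt[b1:b2], "exon"),
        _Segment("i2", _random_dna(rng, 30), "intron"),
        _Segment("E3", nt[b2:], "exon"),
    ]
    return _Plan(
        template="se1ph",
        segments=segments,
        event_type=EventType.SE,
        anchor_names=("E1", "E3"),
        alt_names=("E2",),
        canonical_protein=canonical,
        tier=1,
        included_fate="canonical_dup",
        excluded_fate="novel",
        novel_protein=f0_aa + f1_aa + f2_aa,
    )


def _plan_ri2(rng, cfg):
    """Opt-in frameshifting retained intron (tier 2)."""
    n = cfg.ri_tier2_intron_nt
    u_aa = "M" + _frag(rng, 19)
    d_aa = _frag(rng, 20)
    canonical = u_aa + d_aa
    u_nt = _backtranslate(u_aa, rng)
    for _ in range(300):
        x_nt = _random_dna(rng, n)
        d_nt = _backtranslate(d_aa, rng)
        aa, early_stop = _translate0(u_nt + x_nt + d_nt)
        if not early_stop and aa[-10:] not in canonical:
            segments = [
                _Segment("E1", u_nt, "exon"),
                _Segment("X", x_nt, "extra"),
                _Segment("E2", d_nt + "TAA", "exon"),
            ]
            return _Plan(
                template="ri2",
                segments=segments,
                event_type=EventType.RI,
                anchor_names=("E1", "E2"),
                alt_names=("X",),
                canonical_protein=canonical,
                tier=2,
                included_fate="orphan:c_overhang_unmatched",
                excluded_fate="canonical_dup",
                novel_protein=None,
            )
    raise GenerationError("ri2: could not build a PTC-free frameshifting intron")


_TEMPLATES = {
    "se1": _plan_se1,
    "se1m": _plan_se1m,
    "mxe1": _plan_mxe1,
    "a3ss1": _plan_a3ss1,
    "a5ss1": _plan_a5ss1,
    "ri1": _plan_ri1,
    "se2": _plan_se2,
    "se3": _plan_se3,
    "se4": _plan_se4,
    "se1low": _plan_se1low,
    "se1inc": _plan_se1inc,
    "se1dup": _plan_se1dup,
    "se1noc": _plan_se1noc,
    "se1ph": _plan_se1ph,
    "ri2": _plan_ri2,
}

_MINUS_STRAND_TEMPLATES = {"se1m"}


# ---------------------------------------------------------------------------
# placement


def _mirror(iv: Interval, length: int) -> Interval:
    return Interval(length - iv.end, length - iv.start)


def _place_locus(
    index: int,
    template: str,
    strand: str,
    rng: np.random.Generator,
    cfg: FixtureConfig,
) -> ToyLocus:
    plan = _TEMPLATES[template](rng, cfg)
    pad5 = _random_dna(rng, cfg.pad)
    pad3 = _random_dna(rng, cfg.pad)
    seq_parts = [pad5]
    coords: dict[str, Interval] = {}
    offset = len(pad5)
    for seg in plan.segments:
        coords[seg.name] = Interval(offset, offset + len(seg.seq))
        seq_parts.append(seg.seq)
        offset += len(seg.seq)
    seq_parts.append(pad3)
    contig_seq = "".join(seq_parts)

    exon_names = [s.name for s in plan.segments if s.role in ("exon", "utr_exon")]
    coding_names = [s.name for s in plan.segments if s.role == "exon"]

    # CDS pieces in transcript order; the final piece drops the stop codon
    cds_fw: list[tuple[Interval, int]] = []
    cum = 0
    for i, name in enumerate(coding_names):
        iv = coords[name]
        if i == len(coding_names) - 1:
            iv = Interval(iv.start, iv.end - 3)
        frame = (3 - cum % 3) % 3
        cds_fw.append((iv, frame))
        cum += iv.length

    if strand == "-":
        n = len(contig_seq)
        contig_seq = revcomp(contig_seq)
        coords = {k: _mirror(v, n) for k, v in coords.items()}
        cds = [(_mirror(iv, n), frame) for iv, frame in cds_fw]
    else:
        cds = cds_fw

    return ToyLocus(
        index=index,
        template=template,
        contig=f"chr{index + 1}",
        gene_id=f"GFIX{index + 1:04d}",
        transcript_id=f"TFIX{index + 1:04d}",
        gene_symbol=f"GENE{index + 1}{template.upper()}",
        accession=f"P{index + 1:05d}",
        strand=strand,
        contig_seq=contig_seq,
        exons=[coords[n] for n in exon_names],
        cds=cds,
        canonical_protein=plan.canonical_protein,
        in_proteome=plan.in_proteome,
        plan=plan,
        segment_coords=coords,
    )


def _locus_events(
    locus: ToyLocus,
    rng: np.random.Generator,
    cfg: FixtureConfig,
    id_counters: dict[EventType, int],
) -> list[tuple[SpliceEvent, ReplicateCounts, dict]]:
    plan = locus.plan
    coords = locus.segment_coords
    anchors = tuple(sorted((coords[plan.anchor_names[0]], coords[plan.anchor_names[1]])))
    alts = tuple(sorted(coords[n] for n in plan.alt_names))
    lam = cfg.lambda_high if plan.count_class == "high" else cfg.lambda_low
    out = []
    for _ in range(plan.n_rows):
        id_counters[plan.event_type] = id_counters.get(plan.event_type, 0) + 1
        row_id = id_counters[plan.event_type]
        n_rep = 2 * cfg.replicates_per_sample
        sjc = tuple(int(v) for v in rng.poisson(lam, n_rep))
        ijc = tuple(int(v) for v in rng.poisson(cfg.lambda_high, n_rep))
        event = SpliceEvent(
            event_id=f"{plan.event_type.value}_{row_id}",
            event_type=plan.event_type,
            gene_id=locus.gene_id,
            gene_symbol=locus.gene_symbol,
            chromosome=locus.contig,
            strand=locus.strand,
            anchor_exons=anchors,
            alt_exons=alts,
        )
        counts = ReplicateCounts(
            ijc=ijc, sjc=sjc, p_value=plan.p_value, fdr=plan.p_value
        )
        min_sjc = min(sjc)
        if min_sjc < cfg.manifest_theta:
            verdict = "low_count"
        elif plan.p_value is not None and plan.p_value <= cfg.p_cutoff:
            verdict = "inconsistent"
        else:
            verdict = "kept"
        manifest_row = {
            "event_id": event.event_id,
            "template": plan.template,
            "gene_symbol": locus.gene_symbol,
            "event_type": plan.event_type.value,
            "strand": locus.strand,
            "tier": str(plan.tier),
            "min_sjc": str(min_sjc),
            "p_value": "NA" if plan.p_value is None else str(plan.p_value),
            "verdict": verdict,
            "included_fate": plan.included_fate,
            "excluded_fate": plan.excluded_fate,
            "novel_protein": plan.novel_protein or "-",
        }
        out.append((event, counts, manifest_row))
    return out


# ---------------------------------------------------------------------------
# writers


def _gtf_attrs(**kv: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items())


def _write_gtf(loci: Sequence[ToyLocus], path: Path) -> None:
    lines = ["#!genome-build toy"]
    for locus in loci:
        gene_iv = Interval(
            min(e.start for e in locus.exons), max(e.end for e in locus.exons)
        )
        base = dict(gene_id=locus.gene_id, gene_name=locus.gene_symbol)
        tx = dict(base, transcript_id=locus.transcript_id, tag="Ensembl_canonical")

        def line(feature: str, iv: Interval, frame: str, attrs: dict) -> str:
            return "\t".join(
                [
                    locus.contig, "toy", feature,
                    str(iv.start + 1), str(iv.end),
                    ".", locus.strand, frame,
                    _gtf_attrs(**attrs),
                ]
            )

        lines.append(line("gene", gene_iv, ".", base))
        lines.append(line("transcript", gene_iv, ".", tx))
        for i, exon in enumerate(sorted(locus.exons), 1):
            lines.append(line("exon", exon, ".", dict(tx, exon_number=str(i))))
        for iv, frame in locus.cds:
            lines.append(line("CDS", iv, str(frame), tx))
    path.write_text("\n".join(lines) + "\n")


def _write_genome(loci: Sequence[ToyLocus], path: Path) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(f">{locus.contig}\n{wrap_fasta(locus.contig_seq)}\n")


def _write_proteome(loci: Sequence[ToyLocus], path: Path) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            if not locus.in_proteome:
                continue
            fh.write(
                f">sp|{locus.accession}|{locus.gene_symbol}_TOY toy canonical "
                f"GN={locus.gene_symbol}\n{wrap_fasta(locus.canonical_protein)}\n"
            )


_RMATS_HEADERS = {
    EventType.SE: [
        "ID", "GeneID", "geneSymbol", "chr", "strand",
        "exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ],
    EventType.MXE: [
        "ID", "GeneID", "geneSymbol", "chr", "strand",
        "1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base", "2ndExonEnd",
        "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
    ],
    EventType.A3SS: [
        "ID", "GeneID", "geneSymbol", "chr", "strand",
        "longExonStart_0base", "longExonEnd", "shortES", "shortEE",
        "flankingES", "flankingEE",
    ],
    EventType.A5SS: [
        "ID", "GeneID", "geneSymbol", "chr", "strand",
        "longExonStart_0base", "longExonEnd", "shortES", "shortEE",
        "flankingES", "flankingEE",
    ],
    EventType.RI: [
        "ID", "GeneID", "geneSymbol", "chr", "strand",
        "riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ],
}
_RMATS_TAIL = [
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
    "IncFormLen", "SkipFormLen", "PValue", "FDR",
    "IncLevel1", "IncLevel2", "IncLevelDifference",
]


def _coord_fields(event: SpliceEvent) -> list[str]:
    a1, a2 = event.anchor_exons
    if event.event_type is EventType.SE:
        alt = event.alt_exons[0]
        vals = [alt.start, alt.end, a1.start, a1.end, a2.start, a2.end]
    elif event.event_type is EventType.MXE:
        lo, hi = event.alt_exons
        vals = [lo.start, lo.end, hi.start, hi.end, a1.start, a1.end, a2.start, a2.end]
    elif event.event_type in (EventType.A3SS, EventType.A5SS):
        alt = event.alt_exons[0]
        if alt.end == a1.start or a1.end == alt.start:
            short, flank = a1, a2
        elif alt.end == a2.start or a2.end == alt.start:
            short, flank = a2, a1
        else:
            raise GenerationError("alt segment not adjacent to either anchor")
        long = Interval(min(short.start, alt.start), max(short.end, alt.end))
        vals = [long.start, long.end, short.start, short.end, flank.start, flank.end]
    else:  # RI
        vals = [a1.start, a2.end, a1.start, a1.end, a2.start, a2.end]
    return [str(v) for v in vals]


def _split_half(values: Sequence[int]) -> tuple[str, str]:
    half = len(values) // 2
    return (
        ",".join(str(v) for v in values[:half]),
        ",".join(str(v) for v in values[half:]),
    )


def write_rmats_tables(
    records: dict[EventType, list[tuple[SpliceEvent, ReplicateCounts]]],
    out_dir: str | Path,
) -> dict[EventType, Path]:
    """Emit rMATS-style JC tables (one per AS type, all five always written)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[EventType, Path] = {}
    for etype in EventType:
        path = out_dir / f"{etype.value}.MATS.JC.txt"
        rows = [ "\t".join(_RMATS_HEADERS[etype] + _RMATS_TAIL) ]
        for event, counts in records.get(etype, []):
            ijc1, ijc2 = _split_half(counts.ijc)
            sjc1, sjc2 = _split_half(counts.sjc)
            p = "NA" if counts.p_value is None else repr(counts.p_value)
            fdr = "NA" if counts.fdr is None else repr(counts.fdr)
            inc1, inc2 = "NA", "NA"
            if counts.inc_levels:
                half = len(counts.inc_levels) // 2
                inc1 = ",".join(repr(v) for v in counts.inc_levels[:half]) or "NA"
                inc2 = ",".join(repr(v) for v in counts.inc_levels[half:]) or "NA"
            row = [
                event.event_id.split("_", 1)[1],
                event.gene_id,
                event.gene_symbol,
                event.chromosome,
                event.strand,
                *_coord_fields(event),
                ijc1, sjc1, ijc2, sjc2,
                "100", "50", p, fdr, inc1, inc2, "NA",
            ]
            rows.append("\t".join(row))
        path.write_text("\n".join(rows) + "\n")
        paths[etype] = path
    return paths


def _write_manifest(rows: Sequence[dict], params: dict, path: Path) -> None:
    columns = [
        "event_id", "template", "gene_symbol", "event_type", "strand", "tier",
        "min_sjc", "p_value", "verdict", "included_fate", "excluded_fate",
        "novel_protein",
    ]
    lines = [f"#{k}={v}" for k, v in sorted(params.items())]
    lines.append("\t".join(columns))
    for row in rows:
        lines.append("\t".join(row[c] for c in columns))
    path.write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> tuple[dict, list[dict]]:
    params: dict[str, str] = {}
    rows: list[dict] = []
    header: Optional[list[str]] = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            k, _, v = line[1:].partition("=")
            params[k] = v
        elif header is None:
            header = line.split("\t")
        elif line:
            rows.append(dict(zip(header, line.split("\t"))))
    return params, rows


# ---------------------------------------------------------------------------
# entry points


def generate_fixture(
    n_loci: int,
    seed: int,
    out_dir: str | Path,
    config: Optional[FixtureConfig] = None,
    templates: Optional[Sequence[str]] = None,
    strands: Optional[Sequence[str]] = None,
) -> FixtureBundle:
    """Build a complete toy input bundle with ``n_loci`` planted loci.

    Templates are cycled from the catalogue (or the explicit ``templates``
    list); ``strands`` may override the per-template default strand.
    Regeneration with the same arguments is byte-identical.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    cfg = config or FixtureConfig()
    catalogue = list(templates) if templates else list(TEMPLATE_NAMES)
    if cfg.ri_tier2_intron_nt is not None and "ri2" not in catalogue:
        catalogue.append("ri2")
    for name in catalogue:
        if name not in _TEMPLATES:
            raise GenerationError(f"unknown template {name!r}")
        if name == "ri2" and cfg.ri_tier2_intron_nt is None:
            raise GenerationError("template 'ri2' requires ri_tier2_intron_nt")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    loci: list[ToyLocus] = []
    records: dict[EventType, list[tuple[SpliceEvent, ReplicateCounts]]] = {
        t: [] for t in EventType
    }
    manifest: list[dict] = []
    id_counters: dict[EventType, int] = {}
    for i in range(n_loci):
        template = catalogue[i % len(catalogue)]
        if strands is not None:
            strand = strands[i % len(strands)]
        else:
            strand = "-" if template in _MINUS_STRAND_TEMPLATES else "+"
        rng = np.random.default_rng([seed, i])
        locus = _place_locus(i, template, strand, rng, cfg)
        loci.append(locus)
        for event, counts, row in _locus_events(locus, rng, cfg, id_counters):
            records[event.event_type].append((event, counts))
            manifest.append(row)

    genome_path = out_dir / "genome.fa"
    gtf_path = out_dir / "annotation.gtf"
    proteome_path = out_dir / "proteome.fasta"
    manifest_path = out_dir / "manifest.tsv"
    _write_genome(loci, genome_path)
    _write_gtf(loci, gtf_path)
    _write_proteome(loci, proteome_path)
    write_rmats_tables(records, out_dir)
    _write_manifest(
        manifest,
        {
            "seed": seed,
            "n_loci": n_loci,
            "manifest_theta": cfg.manifest_theta,
            "p_cutoff": cfg.p_cutoff,
            "lambda_low": cfg.lambda_low,
            "lambda_high": cfg.lambda_high,
        },
        manifest_path,
    )
    return FixtureBundle(
        out_dir=out_dir,
        genome_path=genome_path,
        gtf_path=gtf_path,
        proteome_path=proteome_path,
        rmats_dir=out_dir,
        manifest_path=manifest_path,
        manifest=manifest,
        loci=loci,
    )


# -- worked example ---------------------------------------------------------

_WE_LENGTH = 1274
_WE_RT = (272, "RT")  # 0-based offset of printed fragments
_WE_EXCISED = (274, "SLAGGGRRIS")
_WE_DOWNSTREAM = (284, "DSHEDTGILDFSSLLK")
_WE_EXON8_AA = (274, 284)  # residue span encoded by the skippable exon


def mybpc3_worked_example(out_dir: str | Path, seed: int = 0) -> FixtureBundle:
    """Single-gene bundle around the documented MYBPC3 exon-8 skip.

    The canonical protein is 1,274 residues with the published junction
    fragments planted at their stated offsets (RT at 273-274, the excised
    SLAGGGRRIS decapeptide at 275-284 encoded by its own exon, and
    DSHEDTGILDFSSLLK at 285-300); all other residues are seeded filler.
    Skipping the middle exon yields an isoform differing from canonical
    by exactly those 10 residues, whose tryptic digest contains the
    junction-spanning peptide RTDSHEDTGILDFSSLLK.
    """
    rng = np.random.default_rng([seed, 97])
    aa = list(_frag(rng, _WE_LENGTH))
    aa[0] = "M"
    aa[271] = "K"  # tryptic context for the junction peptide
    for offset, frag in (_WE_RT, _WE_EXCISED, _WE_DOWNSTREAM):
        aa[offset : offset + len(frag)] = frag
    aa[300] = "A"  # no proline blocking cleavage after ...SSLLK
    canonical = "".join(aa)
    lo, hi = _WE_EXON8_AA

    segments = [
        _Segment("E1", _backtranslate(canonical[:lo], rng), "exon"),
        _Segment("i1", _random_dna(rng, 60), "intron"),
        _Segment("E2", _backtranslate(canonical[lo:hi], rng), "exon"),
        _Segment("i2", _random_dna(rng, 60), "intron"),
        _Segment("E3", _backtranslate(canonical[hi:], rng) + "TAA", "exon"),
    ]
    plan = _Plan(
        template="mybpc3",
        segments=segments,
        event_type=EventType.SE,
        anchor_names=("E1", "E3"),
        alt_names=("E2",),
        canonical_protein=canonical,
        tier=1,
        included_fate="canonical_dup",
        excluded_fate="novel",
        novel_protein=canonical[:lo] + canonical[hi:],
    )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pad = 50
    coords: dict[str, Interval] = {}
    offset = pad
    parts = [_random_dna(rng, pad)]
    for seg in plan.segments:
        coords[seg.name] = Interval(offset, offset + len(seg.seq))
        parts.append(seg.seq)
        offset += len(seg.seq)
    parts.append(_random_dna(rng, pad))
    exon_names = ["E1", "E2", "E3"]
    cds = []
    cum = 0
    for i, name in enumerate(exon_names):
        iv = coords[name]
        if i == len(exon_names) - 1:
            iv = Interval(iv.start, iv.end - 3)
        cds.append((iv, (3 - cum % 3) % 3))
        cum += iv.length
    locus = ToyLocus(
        index=0,
        template="mybpc3",
        contig="chr11",
        gene_id="GFIXMYBPC3",
        transcript_id="TFIXMYBPC3",
        gene_symbol="MYBPC3",
        accession="PX0001",
        strand="+",
        contig_seq="".join(parts),
        exons=[coords[n] for n in exon_names],
        cds=cds,
        canonical_protein=canonical,
        in_proteome=True,
        plan=plan,
        segment_coords=coords,
    )

    cfg = FixtureConfig()
    id_counters: dict[EventType, int] = {}
    records: dict[EventType, list[tuple[SpliceEvent, ReplicateCounts]]] = {
        t: [] for t in EventType
    }
    manifest: list[dict] = []
    for event, counts, row in _locus_events(locus, rng, cfg, id_counters):
        records[event.event_type].append((event, counts))
        manifest.append(row)

    genome_path = out_dir / "genome.fa"
    gtf_path = out_dir / "annotation.gtf"
    proteome_path = out_dir / "proteome.fasta"
    manifest_path = out_dir / "manifest.tsv"
    _write_genome([locus], genome_path)
    _write_gtf([locus], gtf_path)
    _write_proteome([locus], proteome_path)
    write_rmats_tables(records, out_dir)
    _write_manifest(manifest, {"seed": seed, "worked_example": "mybpc3"}, manifest_path)
    return FixtureBundle(
        out_dir=out_dir,
        genome_path=genome_path,
        gtf_path=gtf_path,
        proteome_path=proteome_path,
        rmats_dir=out_dir,
        manifest_path=manifest_path,
        manifest=manifest,
        loci=[locus],
    )
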