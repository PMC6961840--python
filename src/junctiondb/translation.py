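"""Single-frame translation of slice pairs and four-tier eligibility.

Tier semantics (checked in order):

1. both slices translate in the annotated frame with no frameshift and
   no premature termination codon (PTC);
2. the alternative segment length difference shifts one slice out of
   frame (difference not divisible by 3) yet both translate PTC-free in
   the annotated frame;
3. a single alternative frame, common to both slices, translates both
   PTC-free when the annotated frame does not (or no annotation exists);
   the frame maximizing total PTC-free translated length wins, ties to
   the lower frame index;
4. exactly one slice of the pair hits a PTC; that slice is truncated at
   the stop and both are still emitted.

Pairs where both slices carry a PTC in every usable frame are ineligible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .sequence_retrieval import FrameAnnotation, NucleotideSlice

__all__ = [
    "TranslatedSlice",
    "SlicePairTranslation",
    "DegenerateInputError",
    "translate_in_frame",
    "resolve_pair",
    "CODON_TABLE",
    "STOP_CODONS",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class TranslatedSlice:
    aa_sequence: str
    frame_used: int
    used_annotated_frame: bool
    ptc_found: bool
    frameshift_vs_annotation: bool = False

    def __post_init__(self) -> None:
        bad = set(self.aa_sequence) - set("ACDEFGHIKLMNPQRSTVWYX")
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class SlicePairTranslation:
    event_id: str
    included: Optional[TranslatedSlice]
    excluded: Optional[TranslatedSlice]
    tier: Optional[int]
    eligible: bool
    reason: Optional[str] = None  # set when ineligible

    def __post_init__(self) -> None:
        if self.eligible != (self.tier is not None):
            raise ValueError("tier must be assigned iff eligible")
        if self.tier is not None and self.tier not in (1, 2, 3, 4):
            raise ValueError(f"tier out of range: {self.tier}")


def translate_in_frame(nt: str, phase: int) -> TranslatedSlice:
    """Translate from ``phase`` bases in, stopping at the first stop codon.

    ``ptc_found`` is set only when the stop occurs before the final
    complete codon position (a terminal stop is a normal terminator).
    Codons containing N translate as 'X'; a trailing incomplete codon is
    ignored.
    """
    if phase not in (0, 1, 2):
        raise ValueError(f"phase must be 0, 1 or 2 (got {phase})")
    nt = nt.upper()
    if len(nt) < phase + 3:
        raise DegenerateInputError(
            f"slice of {len(nt)} nt too short to translate at phase {phase}"
        )
    n_codons = (len(nt) - phase) // 3
    residues: list[str] = []
    ptc = False
    for i in range(n_codons):
        codon = nt[phase + 3 * i : phase + 3 * i + 3]
        if codon in STOP_CODONS:
            ptc = i < n_codons - 1
            break
        residues.append(CODON_TABLE.get(codon, "X"))
    return TranslatedSlice(
        aa_sequence="".join(residues),
        frame_used=phase,
        used_annotated_frame=False,
        ptc_found=ptc,
    )


def _try_frame(inc_nt: str, exc_nt: str, frame: int) -> Optional[tuple[TranslatedSlice, TranslatedSlice]]:
    try:
        return translate_in_frame(inc_nt, frame), translate_in_frame(exc_nt, frame)
    except DegenerateInputError:
        return None


def resolve_pair(
    included_nt: NucleotideSlice,
    excluded_nt: NucleotideSlice,
    frame: FrameAnnotation,
) -> SlicePairTranslation:
    """Resolve one common reading frame for a slice pair and assign its tier."""
    if included_nt.event_id != excluded_nt.event_id:
        raise ValueError("slices come from different events")
    event_id = included_nt.event_id
    inc_nt, exc_nt = included_nt.sequence, excluded_nt.sequence
    shift = (len(inc_nt) - len(exc_nt)) % 3 != 0

    annotated_phase: Optional[int] = frame.phase if frame.annotated else None

    if annotated_phase is not None:
        pair = _try_frame(inc_nt, exc_nt, annotated_phase)
        if pair is not None:
            ti, te = (
                replace(
                    p, used_annotated_frame=True, frameshift_vs_annotation=shift
                )
                for p in pair
            )
            if not ti.ptc_found and not te.ptc_found:
                tier = 2 if shift else 1
                return SlicePairTranslation(event_id, ti, te, tier, True)
            annotated_result = (ti, te)
        else:
            annotated_result = None
    else:
        annotated_result = None

    # tier 3: one common frame, different from (or absent) annotation,
    # translating both PTC-free; maximize total length, ties -> lower frame
    best: Optional[tuple[int, int, TranslatedSlice, TranslatedSlice]] = None
    for f in (0, 1, 2):
        if f == annotated_phase:
            continue
        pair = _try_frame(inc_nt, exc_nt, f)
        if pair is None:
            continue
        ti, te = pair
        if ti.ptc_found or te.ptc_found:
            continue
        total = len(ti.aa_sequence) + len(te.aa_sequence)
        if best is None or total > best[0]:
            best = (total, f, ti, te)
    if best is not None:
        _, f, ti, te = best
        ti = replace(ti, frameshift_vs_annotation=shift)
        te = replace(te, frameshift_vs_annotation=shift)
        return SlicePairTranslation(event_id, ti, te, 3, True)

    # tier 4: exactly one slice carries a PTC in the reference frame
    if annotated_result is not None:
        ti, te = annotated_result
        if ti.ptc_found != te.ptc_found:
            return SlicePairTranslation(event_id, ti, te, 4, True)
        return SlicePairTranslation(
            event_id, ti, te, None, False, reason="both_ptc"
        )

    # no annotation: pick the frame with the longest total pre-stop
    # translation; tier 4 if exactly one side stopped early there
    fallback: Optional[tuple[int, int, TranslatedSlice, TranslatedSlice]] = None
    for f in (0, 1, 2):
        pair = _try_frame(inc_nt, exc_nt, f)
        if pair is None:
            continue
        ti, te = pair
        total = len(ti.aa_sequence) + len(te.aa_sequence)
        if fallback is None or total > fallback[0]:
            fallback = (total, f, ti, te)
    if fallback is not None:
        _, f, ti, te = fallback
        if ti.ptc_found != te.ptc_found:
            ti = replace(ti, frameshift_vs_annotation=shift)
            te = replace(te, frameshift_vs_annotation=shift)
            return SlicePairTranslation(event_id, ti, te, 4, True)
        return SlicePairTranslation(event_id, ti, te, None, False, reason="both_ptc")
    return SlicePairTranslation(
        event_id, None, None, None, False, reason="untranslatable"
    )
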