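"""Small shared helpers: nucleotide arithmetic and tryptic digestion."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def wrap_fasta(seq: str, width: int = 60) -> str:
    """Wrap a sequence at ``width`` columns, newline-joined, no trailing newline."""
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def tryptic_peptides(protein: str, missed_cleavages: int = 1, min_length: int = 6) -> set[str]:
    """Enumerate tryptic peptides of a protein.

    Cleaves C-terminal to K or R, except when the next residue is P.
    Peptides with up to ``missed_cleavages`` internal uncut sites are included.
    """
    cuts = [0]
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    peptides: set[str] = set()
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
            pep = protein[cuts[i] : cuts[j]]
            if len(pep) >= min_length:
                peptides.add(pep)
    return peptides
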