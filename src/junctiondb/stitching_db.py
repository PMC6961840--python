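"""Stitch translated slices onto canonical proteins and write the FASTA.

A translated slice is extended to a full-length protein by locating its
N-terminal and C-terminal 10-mers (overhang) as exact substrings of the
matched canonical sequence and splicing the slice in between. Slices
whose overhangs cannot both be placed in order are orphans and are
discarded (with a reason). Identical products are merged, products equal
to a canonical sequence are flagged, and the database is written as
60-column FASTA with an optional companion of reversed decoys.

Header grammar for noncanonical entries::

    >sp|{accession}-{event_type}{n}|{gene}_{tier} {chrom}:{start}-{end}:{strand}

entries identical to canonical carry ``canonical`` in place of the tier.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO

from .rmats_io import EventType, SpliceEvent
from .translation import TranslatedSlice
from .utils import wrap_fasta

__all__ = [
    "CanonicalRecord",
    "IsoformEntry",
    "OrphanVerdict",
    "DEFAULT_OVERHANG",
    "DECOY_PREFIX",
    "load_canonical_fasta",
    "stitch",
    "deduplicate",
    "write_database",
    "read_database",
]

logger = logging.getLogger(__name__)

DEFAULT_OVERHANG = 10
DECOY_PREFIX = "DECOY_"

_GN_RE = re.compile(r"\bGN=(\S+)")
_SP_RE = re.compile(r"^(?:sp|tr)\|([^|]+)\|(\S+)")


@dataclass(frozen=True)
class CanonicalRecord:
    accession: str
    gene_symbol: str
    aa_sequence: str
    header: str

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            raise ValueError(f"empty canonical sequence for {self.accession}")


@dataclass(frozen=True)
class IsoformEntry:
    aa_sequence: str
    gene_symbol: str
    canonical_accession: str
    event_ids: tuple[str, ...]
    event_type: EventType
    tier: int
    slice_region: tuple[int, int]  # half-open residue interval in aa_sequence
    genomic_tag: str  # "chrom:start-end:strand"
    is_canonical_duplicate: bool = False


@dataclass(frozen=True)
class OrphanVerdict:
    event_id: str
    which: str
    reason: str  # too_short | no_canonical | n_overhang_unmatched | c_overhang_unmatched


def load_canonical_fasta(path: str | Path) -> list[CanonicalRecord]:
    """Read a canonical proteome FASTA, tolerating UniProt or bare headers.

    The gene symbol is taken from the ``GN=`` token when present, else
    from the record name.
    """
    records: list[CanonicalRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        m = _SP_RE.match(header)
        accession = m.group(1) if m else rec.id
        gn = _GN_RE.search(header)
        if gn:
            symbol = gn.group(1)
        elif m:
            symbol = m.group(2).split("_")[0]
        else:
            symbol = rec.id
        records.append(
            CanonicalRecord(
                accession=accession,
                gene_symbol=symbol,
                aa_sequence=str(rec.seq).upper().rstrip("*"),
                header=header,
            )
        )
    return records


def genomic_tag(event: SpliceEvent) -> str:
    span = event.span
    return f"{event.chromosome}:{span.start}-{span.end}:{event.strand}"


def stitch(
    t_slice: TranslatedSlice,
    canonical: CanonicalRecord,
    overhang: int = DEFAULT_OVERHANG,
    *,
    event: SpliceEvent,
    which: str,
    tier: int,
) -> Union[IsoformEntry, OrphanVerdict]:
    """Extend one translated slice to full length via exact overhang match.

    The slice's first ``overhang`` residues must occur in the canonical
    sequence, and its last ``overhang`` residues must occur again at a
    strictly later start; first occurrences win. The product is
    ``canonical[:n_start] + slice + canonical[c_start+overhang:]``.
    """
    if overhang < 1:
        raise ValueError("overhang must be positive")
    s = t_slice.aa_sequence
    if len(s) < 2 * overhang:
        return OrphanVerdict(event.event_id, which, "too_short")
    c = canonical.aa_sequence
    n_start = c.find(s[:overhang])
    if n_start < 0:
        return OrphanVerdict(event.event_id, which, "n_overhang_unmatched")
    c_start = c.find(s[-overhang:], n_start + 1)
    if c_start < 0:
        return OrphanVerdict(event.event_id, which, "c_overhang_unmatched")
    product = c[:n_start] + s + c[c_start + overhang :]
    return IsoformEntry(
        aa_sequence=product,
        gene_symbol=canonical.gene_symbol,
        canonical_accession=canonical.accession,
        event_ids=(event.event_id,),
        event_type=event.event_type,
        tier=tier,
        slice_region=(n_start, n_start + len(s)),
        genomic_tag=genomic_tag(event),
        is_canonical_duplicate=(product == c),
    )


def deduplicate(
    entries: Sequence[IsoformEntry],
    canonicals: Sequence[CanonicalRecord],
) -> list[IsoformEntry]:
    """Merge entries with identical sequences; flag canonical-identical ones.

    Provenance (event id) lists are concatenated in first-seen order and
    the best (lowest) tier is retained. Output order is deterministic:
    by gene symbol, accession, then first event id.
    """
    canonical_seqs = {c.aa_sequence for c in canonicals}
    merged: dict[str, IsoformEntry] = {}
    for entry in entries:
        key = entry.aa_sequence
        if key in merged:
            prev = merged[key]
            ids = prev.event_ids + tuple(
                e for e in entry.event_ids if e not in prev.event_ids
            )
            keep = prev if prev.tier <= entry.tier else entry
            merged[key] = replace(keep, event_ids=ids)
        else:
            merged[key] = entry
        if key in canonical_seqs and not merged[key].is_canonical_duplicate:
            merged[key] = replace(merged[key], is_canonical_duplicate=True)
    return sorted(
        merged.values(),
        key=lambda e: (e.gene_symbol, e.canonical_accession, e.event_ids[0]),
    )


def _entry_header(entry: IsoformEntry, n: int) -> str:
    label = "canonical" if entry.is_canonical_duplicate else str(entry.tier)
    return (
        f"sp|{entry.canonical_accession}-{entry.event_type.value}{n}|"
        f"{entry.gene_symbol}_{label} {entry.genomic_tag}"
    )


def write_database(
    entries: Sequence[IsoformEntry],
    canonicals: Sequence[CanonicalRecord],
    out_path: str | Path,
    include_decoys: bool = False,
) -> list[Path]:
    """Write the target FASTA (and, optionally, the reversed-decoy FASTA).

    Decoy records reverse each target sequence and prefix the accession
    field with ``DECOY_``. Returns the list of files written.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if not entries:
        logger.warning("writing empty database to %s", out_path)

    counters: dict[tuple[str, str], int] = {}
    headers: list[str] = []
    for entry in entries:
        key = (entry.canonical_accession, entry.event_type.value)
        counters[key] = counters.get(key, 0) + 1
        headers.append(_entry_header(entry, counters[key]))

    with open(out_path, "w") as fh:
        for header, entry in zip(headers, entries):
            fh.write(f">{header}\n")
            if entry.aa_sequence:
                fh.write(wrap_fasta(entry.aa_sequence) + "\n")
    written = [out_path]

    if include_decoys:
        decoy_path = out_path.with_suffix(out_path.suffix + ".decoy.fasta")
        with open(decoy_path, "w") as fh:
            for header, entry in zip(headers, entries):
                fh.write(f">{DECOY_PREFIX}{header}\n")
                if entry.aa_sequence:
                    fh.write(wrap_fasta(entry.aa_sequence[::-1]) + "\n")
        written.append(decoy_path)
    return written


_HEADER_RE = re.compile(
    r"^sp\|(?P<accession>[^-|]+)-(?P<etype>SE|MXE|A3SS|A5SS|RI)(?P<n>\d+)\|"
    r"(?P<gene>\S+)_(?P<label>canonical|[1-4]) "
    r"(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>[+-])$"
)


def read_database(path: str | Path) -> list[dict]:
    """Parse back a database written by :func:`write_database`."""
    out: list[dict] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _HEADER_RE.match(rec.description)
        if not m:
            raise ValueError(f"unparseable database header: {rec.description!r}")
        d = m.groupdict()
        out.append(
            {
                "accession": d["accession"],
                "event_type": EventType(d["etype"]),
                "index": int(d["n"]),
                "gene_symbol": d["gene"],
                "is_canonical_duplicate": d["label"] == "canonical",
                "tier": None if d["label"] == "canonical" else int(d["label"]),
                "chromosome": d["chrom"],
                "start": int(d["start"]),
                "end": int(d["end"]),
                "strand": d["strand"],
                "aa_sequence": str(rec.seq),
            }
        )
    return out
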