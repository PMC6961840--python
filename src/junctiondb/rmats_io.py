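"""Readers for rMATS alternative-splicing event tables (JC dialect).

One tab-separated file per AS type (``SE.MATS.JC.txt`` and friends). Each
row yields a :class:`SpliceEvent` (genomic geometry) plus a
:class:`ReplicateCounts` (per-replicate junction read counts and rMATS
statistics). rMATS start columns are 0-based and end columns 1-based
inclusive, which is numerically identical to the 0-based half-open
convention used internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "EventType",
    "Interval",
    "SpliceEvent",
    "ReplicateCounts",
    "RmatsFormatError",
    "RmatsRowError",
    "parse_rmats_table",
    "min_skipped_count",
    "rmats_filename",
]


class EventType(str, Enum):
    SE = "SE"
    MXE = "MXE"
    A3SS = "A3SS"
    A5SS = "A5SS"
    RI = "RI"


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"empty or negative interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


# alt_exon arity per event type (A3SS/A5SS carry the single differential
# segment between the long and short form; the shared short exon is an anchor)
ALT_ARITY = {
    EventType.SE: 1,
    EventType.MXE: 2,
    EventType.A3SS: 1,
    EventType.A5SS: 1,
    EventType.RI: 1,
}


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    event_type: EventType
    gene_id: str
    gene_symbol: str
    chromosome: str
    strand: str
    anchor_exons: tuple[Interval, Interval]  # genomic order: (left, right)
    alt_exons: tuple[Interval, ...]  # genomic order

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if len(self.alt_exons) != ALT_ARITY[self.event_type]:
            raise ValueError(
                f"{self.event_type.value} event requires "
                f"{ALT_ARITY[self.event_type]} alt exon(s), got {len(self.alt_exons)}"
            )
        left, right = self.anchor_exons
        if left.start > right.start:
            raise ValueError("anchor exons must be in genomic order")

    @property
    def upstream_anchor(self) -> Interval:
        """Anchor exon at the transcript 5' side (strand-aware)."""
        return self.anchor_exons[0] if self.strand == "+" else self.anchor_exons[1]

    @property
    def span(self) -> Interval:
        blocks = list(self.anchor_exons) + list(self.alt_exons)
        return Interval(min(b.start for b in blocks), max(b.end for b in blocks))


@dataclass(frozen=True)
class ReplicateCounts:
    ijc: tuple[int, ...]
    sjc: tuple[int, ...]
    inc_levels: tuple[float, ...] = ()
    p_value: Optional[float] = None
    fdr: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.ijc) != len(self.sjc) or len(self.sjc) == 0:
            raise ValueError("ijc and sjc must have equal, nonzero length")
        if any(c < 0 for c in self.ijc + self.sjc):
            raise ValueError("junction counts must be non-negative")
        for v in (self.p_value, self.fdr):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"p/fdr outside [0,1]: {v}")


class RmatsFormatError(ValueError):
    """Table-level problem (e.g. a required column is missing)."""


class RmatsRowError(ValueError):
    """Row-level problem; carries the 0-based data-row index."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


_COORD_COLUMNS = {
    EventType.SE: [
        "exonStart_0base", "exonEnd",
        "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
    ],
    EventType.MXE: [
        "1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base", "2ndExonEnd",
        "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
    ],
    EventType.A3SS: [
        "longExonStart_0base", "longExonEnd", "shortES", "shortEE",
        "flankingES", "flankingEE",
    ],
    EventType.A5SS: [
        "longExonStart_0base", "longExonEnd", "shortES", "shortEE",
        "flankingES", "flankingEE",
    ],
    EventType.RI: [
        "riExonStart_0base", "riExonEnd",
        "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
    ],
}

_COMMON_COLUMNS = [
    "ID", "GeneID", "geneSymbol", "chr", "strand",
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
    "PValue", "FDR",
]


def rmats_filename(event_type: EventType) -> str:
    return f"{event_type.value}.MATS.JC.txt"


def _split_counts(raw: object) -> tuple[int, ...]:
    # sample-2 column may be empty or NA when rMATS ran single-sample
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return ()
    text = str(raw).strip()
    if not text or text.upper() == "NA":
        return ()
    parts = [p for p in text.split(",") if p != ""]
    values = tuple(int(p) for p in parts)
    if any(v < 0 for v in values):
        raise ValueError(f"negative count in {text!r}")
    return values


def _split_fracs(raw: object) -> tuple[float, ...]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return ()
    text = str(raw).strip()
    if not text or text.upper() == "NA":
        return ()
    return tuple(float(p) for p in text.split(",") if p not in ("", "NA"))


def _opt_float(raw: object) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if not text or text.upper() == "NA":
        return None
    return float(text)


def _geometry(row: pd.Series, event_type: EventType) -> tuple[tuple[Interval, Interval], tuple[Interval, ...]]:
    def iv(a: str, b: str) -> Interval:
        return Interval(int(row[a]), int(row[b]))

    if event_type is EventType.SE:
        anchors = sorted([iv("upstreamES", "upstreamEE"), iv("downstreamES", "downstreamEE")])
        alts = (iv("exonStart_0base", "exonEnd"),)
    elif event_type is EventType.MXE:
        anchors = sorted([iv("upstreamES", "upstreamEE"), iv("downstreamES", "downstreamEE")])
        alts = tuple(sorted([iv("1stExonStart_0base", "1stExonEnd"), iv("2ndExonStart_0base", "2ndExonEnd")]))
    elif event_type in (EventType.A3SS, EventType.A5SS):
        long = iv("longExonStart_0base", "longExonEnd")
        short = iv("shortES", "shortEE")
        flank = iv("flankingES", "flankingEE")
        if not long.contains(short):
            raise ValueError("short exon not contained in long exon")
        if long.start == short.start and long.end > short.end:
            alt = Interval(short.end, long.end)
        elif long.end == short.end and long.start < short.start:
            alt = Interval(long.start, short.start)
        else:
            raise ValueError("long/short exons do not share a boundary")
        anchors = sorted([flank, short])
        alts = (alt,)
    else:  # RI
        up = iv("upstreamES", "upstreamEE")
        down = iv("downstreamES", "downstreamEE")
        ri = iv("riExonStart_0base", "riExonEnd")
        up, down = sorted([up, down])
        if ri.start != up.start or ri.end != down.end:
            raise ValueError("riExon does not span the flanking exons")
        if up.end >= down.start:
            raise ValueError("no intron between flanking exons")
        anchors = [up, down]
        alts = (Interval(up.end, down.start),)
    return (anchors[0], anchors[1]), alts


def parse_rmats_table(
    path: str | Path,
    event_type: EventType,
    row_errors: Optional[list[RmatsRowError]] = None,
) -> list[tuple[SpliceEvent, ReplicateCounts]]:
    """Parse one rMATS JC table into (event, counts) records.

    Both sample columns are concatenated into one replicate list (the
    intended use is replicates of a single tissue). Malformed rows raise
    :class:`RmatsRowError` unless ``row_errors`` is given, in which case
    they are collected there and the row is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = _COMMON_COLUMNS + _COORD_COLUMNS[event_type]
    for col in required:
        if col not in table.columns:
            raise RmatsFormatError(f"{path.name}: missing required column {col!r}")

    records: list[tuple[SpliceEvent, ReplicateCounts]] = []
    for i, row in table.iterrows():
        try:
            ijc = _split_counts(row["IJC_SAMPLE_1"]) + _split_counts(row["IJC_SAMPLE_2"])
            sjc = _split_counts(row["SJC_SAMPLE_1"]) + _split_counts(row["SJC_SAMPLE_2"])
            if len(ijc) != len(sjc):
                raise ValueError(f"IJC has {len(ijc)} replicates but SJC has {len(sjc)}")
            inc = _split_fracs(row.get("IncLevel1", "")) + _split_fracs(row.get("IncLevel2", ""))
            anchors, alts = _geometry(row, event_type)
            event = SpliceEvent(
                event_id=f"{event_type.value}_{row['ID']}",
                event_type=event_type,
                gene_id=str(row["GeneID"]).strip('"'),
                gene_symbol=str(row["geneSymbol"]).strip('"'),
                chromosome=str(row["chr"]),
                strand=str(row["strand"]),
                anchor_exons=anchors,
                alt_exons=alts,
            )
            counts = ReplicateCounts(
                ijc=ijc,
                sjc=sjc,
                inc_levels=inc,
                p_value=_opt_float(row["PValue"]),
                fdr=_opt_float(row["FDR"]),
            )
        except (ValueError, KeyError) as exc:
            err = RmatsRowError(int(i), str(exc))
            if row_errors is None:
                raise err from exc
            row_errors.append(err)
            continue
        records.append((event, counts))
    return records


def min_skipped_count(counts: ReplicateCounts) -> int:
    """Minimum skipped-junction read count over all replicates."""
    if not counts.sjc:
        raise ValueError("no replicate SJC values")
    return min(counts.sjc)
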