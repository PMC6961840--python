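"""End-to-end orchestration: parse -> threshold -> filter -> slice ->
translate -> stitch -> deduplicate -> write."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import junction_filter, rmats_io, sequence_retrieval, stitching_db, translation
from .junction_filter import CountThreshold
from .rmats_io import EventType, ReplicateCounts, SpliceEvent
from .sequence_retrieval import AnnotationIndex, GenomeResource
from .stitching_db import CanonicalRecord, IsoformEntry, OrphanVerdict

__all__ = ["RunConfig", "RunSummary", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

ALL_TYPES = tuple(EventType)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, record_id: str, message: str):
        super().__init__(f"[{stage}] {record_id}: {message}")
        self.stage = stage
        self.record_id = record_id


@dataclass(frozen=True)
class RunConfig:
    rmats_dir: Path
    genome: Path
    gtf: Path
    canonical: Path
    out_dir: Path
    posterior_cutoff: float = 0.95
    p_cutoff: float = 0.01
    manual_theta: Optional[int] = None
    overhang: int = 10
    include_decoys: bool = False
    seed: int = 0
    event_types: tuple[EventType, ...] = ALL_TYPES

    def __post_init__(self) -> None:
        if not self.event_types:
            raise ValueError("event_types mask must not be empty")


@dataclass
class RunSummary:
    theta: int = 0
    threshold: Optional[CountThreshold] = None
    parsed_per_type: dict[str, int] = field(default_factory=dict)
    parse_row_errors: int = 0
    kept: int = 0
    rejected_by_reason: dict[str, int] = field(default_factory=dict)
    eligible_pairs: int = 0
    ineligible_pairs: int = 0
    tier_counts: dict[int, int] = field(default_factory=dict)
    slices_stitched: int = 0
    orphans: int = 0
    entries_written: int = 0
    canonical_duplicates: int = 0
    database_path: Optional[Path] = None
    decoy_path: Optional[Path] = None
    entries: list[IsoformEntry] = field(default_factory=list)

    @property
    def parsed_total(self) -> int:
        return sum(self.parsed_per_type.values())

    def as_tsv(self) -> str:
        rows = [("stage", "key", "count")]
        for etype, n in sorted(self.parsed_per_type.items()):
            rows.append(("parse", etype, n))
        rows.append(("parse", "row_errors", self.parse_row_errors))
        rows.append(("threshold", "theta", self.theta))
        rows.append(("filter", "kept", self.kept))
        for reason, n in sorted(self.rejected_by_reason.items()):
            rows.append(("filter", reason, n))
        rows.append(("translate", "eligible_pairs", self.eligible_pairs))
        rows.append(("translate", "ineligible_pairs", self.ineligible_pairs))
        for tier, n in sorted(self.tier_counts.items()):
            rows.append(("translate", f"tier_{tier}", n))
        rows.append(("stitch", "stitched_slices", self.slices_stitched))
        rows.append(("stitch", "orphans", self.orphans))
        rows.append(("write", "entries", self.entries_written))
        rows.append(("write", "canonical_duplicates", self.canonical_duplicates))
        return "\n".join("\t".join(str(v) for v in row) for row in rows) + "\n"


def _canonical_candidates(
    by_symbol: dict[str, list[CanonicalRecord]], symbol: str
) -> list[CanonicalRecord]:
    # several records may share a symbol: try longest first
    return sorted(
        by_symbol.get(symbol, []), key=lambda c: (-len(c.aa_sequence), c.accession)
    )


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the full database build; returns per-stage counts.

    Writes into ``config.out_dir``: ``database.fasta`` (plus
    ``database.fasta.decoy.fasta`` when decoys are enabled),
    ``threshold.txt``, ``rejects.tsv`` (one audited row per discarded
    record) and ``summary.tsv``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary()
    rejects: list[tuple[str, str, str]] = []  # (stage, record id, reason)

    # -- parse -------------------------------------------------------------
    events: list[tuple[SpliceEvent, ReplicateCounts]] = []
    row_errors: list[rmats_io.RmatsRowError] = []
    for etype in config.event_types:
        path = Path(config.rmats_dir) / rmats_io.rmats_filename(etype)
        if not path.exists():
            logger.warning("no %s table at %s; skipping", etype.value, path)
            summary.parsed_per_type[etype.value] = 0
            continue
        errs: list[rmats_io.RmatsRowError] = []
        parsed = rmats_io.parse_rmats_table(path, etype, row_errors=errs)
        for err in errs:
            rejects.append(("parse", f"{etype.value}:{err.row}", str(err)))
        row_errors.extend(errs)
        summary.parsed_per_type[etype.value] = len(parsed)
        events.extend(parsed)
    summary.parse_row_errors = len(row_errors)
    if summary.parsed_total == 0 and not row_errors:
        raise PipelineError("parse", str(config.rmats_dir), "no events parsed")

    # -- threshold ---------------------------------------------------------
    if config.manual_theta is not None:
        threshold = junction_filter.manual_threshold(
            config.manual_theta, config.posterior_cutoff
        )
    else:
        min_counts = [rmats_io.min_skipped_count(c) for _, c in events]
        threshold = junction_filter.fit_count_mixture(
            min_counts, config.posterior_cutoff, config.seed
        )
    summary.theta = threshold.theta
    summary.threshold = threshold
    (out_dir / "threshold.txt").write_text(threshold.report())

    # -- filter ------------------------------------------------------------
    kept, rejected = junction_filter.filter_events(events, threshold, config.p_cutoff)
    summary.kept = len(kept)
    for rej in rejected:
        summary.rejected_by_reason[rej.reason] = (
            summary.rejected_by_reason.get(rej.reason, 0) + 1
        )
        rejects.append(("filter", rej.event.event_id, rej.reason))

    # -- resources ---------------------------------------------------------
    genome = GenomeResource(config.genome)
    annotation = AnnotationIndex(config.gtf)
    canonicals = stitching_db.load_canonical_fasta(config.canonical)
    by_symbol: dict[str, list[CanonicalRecord]] = {}
    for rec in canonicals:
        by_symbol.setdefault(rec.gene_symbol, []).append(rec)

    # -- slice, translate, stitch -----------------------------------------
    entries: list[IsoformEntry] = []
    for event, _counts in kept:
        try:
            frame = sequence_retrieval.annotate_frame(event, annotation)
        except sequence_retrieval.GeneNotFoundError:
            rejects.append(("annotate", event.event_id, "gene_not_in_gtf"))
            summary.ineligible_pairs += 1
            continue
        try:
            included, excluded = sequence_retrieval.build_slices(event, genome, frame)
        except sequence_retrieval.SliceQualityError:
            rejects.append(("slice", event.event_id, "low_quality"))
            summary.ineligible_pairs += 1
            continue
        except sequence_retrieval.CoordinateError as exc:
            raise PipelineError("slice", event.event_id, str(exc)) from exc

        pair = translation.resolve_pair(included, excluded, frame)
        if not pair.eligible:
            summary.ineligible_pairs += 1
            rejects.append(("translate", event.event_id, pair.reason or "ineligible"))
            continue
        summary.eligible_pairs += 1
        summary.tier_counts[pair.tier] = summary.tier_counts.get(pair.tier, 0) + 1

        for which, t_slice in (("included", pair.included), ("excluded", pair.excluded)):
            candidates = _canonical_candidates(by_symbol, event.gene_symbol)
            if not candidates:
                summary.orphans += 1
                rejects.append(("stitch", f"{event.event_id}/{which}", "no_canonical"))
                continue
            result: OrphanVerdict | IsoformEntry | None = None
            for canonical in candidates:
                result = stitching_db.stitch(
                    t_slice,
                    canonical,
                    config.overhang,
                    event=event,
                    which=which,
                    tier=pair.tier,
                )
                if isinstance(result, IsoformEntry):
                    break
            if isinstance(result, IsoformEntry):
                summary.slices_stitched += 1
                entries.append(result)
            else:
                summary.orphans += 1
                rejects.append(("stitch", f"{event.event_id}/{which}", result.reason))

    # -- deduplicate and write --------------------------------------------
    unique = stitching_db.deduplicate(entries, canonicals)
    summary.entries = unique
    summary.entries_written = len(unique)
    summary.canonical_duplicates = sum(e.is_canonical_duplicate for e in unique)
    db_path = out_dir / "database.fasta"
    written = stitching_db.write_database(
        unique, canonicals, db_path, include_decoys=config.include_decoys
    )
    summary.database_path = written[0]
    if config.include_decoys:
        summary.decoy_path = written[1]

    with open(out_dir / "rejects.tsv", "w") as fh:
        fh.write("stage\trecord\treason\n")
        for stage, record, reason in rejects:
            fh.write(f"{stage}\t{record}\t{reason}\n")
    (out_dir / "summary.tsv").write_text(summary.as_tsv())
    genome.close()
    return summary
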