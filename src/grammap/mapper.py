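"""End-to-end all-mapping of reads against an indexed genome.

For each read and each strand the mapper picks the strongest available
filter path from the read's length:

* ``floor(|r|/q) >= k+2`` — optimal k+2 non-overlapping grams, two-vote
  additional-prefix filter (with the singleton-pair relaxation in edit
  mode);
* ``floor(|r|/q) >= k+1`` — optimal k+1 non-overlapping grams, lossless
  pigeonhole union;
* otherwise — no filtering: every genome window position is verified
  (safe-but-slow degenerate path for short or N-ridden reads; reads
  shorter than q are reported unmapped).

The gate is evaluated per read, so variable-length input is handled
safely.  Candidates are verified (Hamming check or the two-window
banded semi-global heuristic), strands merged, and results
deduplicated by (reference, start, strand).  In m-mapping mode a read
whose distinct mapping-location count exceeds m is suppressed
entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from . import candidates as cand
from . import prefix_selection as psel
from .errors import NotEnoughGramsError
from .reference_index import GenomeIndex, reverse_complement
from .verification import AlignmentResult, verify_candidate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadRecord:
    """One input read (qualities optional; FASTA reads have none)."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"read {self.id!r}: quality length != sequence length")


@dataclass
class MappingReport:
    """All mapping locations of one read, plus bookkeeping counters."""

    read: ReadRecord
    results: list[AlignmentResult] = field(default_factory=list)
    unmapped: bool = False
    suppressed_by_m: bool = False
    candidates_generated: int = 0
    candidates_verified: int = 0


def _strand_candidates(
    seq: str, index: GenomeIndex, k: int, mode: str
) -> list[cand.CandidateLocation]:
    """Candidate starts for one oriented read sequence."""
    q = index.q
    available = psel.max_nonoverlapping_grams(len(seq), q)
    if available >= k + 2:
        try:
            sel = psel.select_prefix_grams(seq, index, k + 2)
            return cand.additional_prefix_candidates(sel, index, k, mode=mode)
        except NotEnoughGramsError:
            pass  # N bases starved the selection; fall through
    if available >= k + 1:
        try:
            sel = psel.select_prefix_grams(seq, index, k + 1)
            return cand.prefix_union_candidates(sel, index)
        except NotEnoughGramsError:
            pass
    # degenerate path: no filtering, every window position is a candidate
    slack = k if mode == "edit" else 0
    max_start = index.total_length - max(1, len(seq) - slack)
    return [
        cand.CandidateLocation(location=p, votes=1) for p in range(0, max_start + 1)
    ]


def map_read(
    read: ReadRecord,
    index: GenomeIndex,
    k: int,
    mode: str = "edit",
    m: int | None = None,
) -> MappingReport:
    """Find all mapping locations of one read within distance k."""
    report = MappingReport(read=read)
    if len(read.seq) < index.q:
        logger.warning(
            "read %s (length %d) is shorter than q=%d; reported unmapped",
            read.id, len(read.seq), index.q,
        )
        report.unmapped = True
        return report

    best: dict[tuple[str, int, str], AlignmentResult] = {}
    for strand in "+-":
        seq = read.seq.upper()
        if strand == "-":
            seq = reverse_complement(seq)
        cands = _strand_candidates(seq, index, k, mode)
        report.candidates_generated += len(cands)
        for candidate in cands:
            hits = verify_candidate(seq, index, candidate, k, mode=mode, strand=strand)
            report.candidates_verified += 1
            for hit in hits:
                key = (hit.ref_name, hit.start, hit.strand)
                old = best.get(key)
                if old is None or (hit.distance, hit.cigar) < (old.distance, old.cigar):
                    best[key] = hit

    report.results = sorted(
        best.values(), key=lambda r: (r.start, r.strand, r.cigar)
    )
    if not report.results:
        report.unmapped = True
    elif m is not None:
        distinct = {(r.ref_name, r.start) for r in report.results}
        if len(distinct) > m:
            report.suppressed_by_m = True
            report.results = []
    return report


def map_all(
    reads: Iterable[ReadRecord],
    index: GenomeIndex,
    k: int,
    mode: str = "edit",
    m: int | None = None,
    workers: int = 1,
) -> Iterator[MappingReport]:
    """Map a stream of reads, yielding one report per read in input order.

    Reads are mutually independent, so the output is identical for any
    ``workers`` value; the parameter is an opaque throughput knob and
    execution is sequential here.  Malformed records are skipped with a
    warning.
    """
    if workers < 1:
        raise ValueError("workers must be >= 1")
    for read in reads:
        try:
            yield map_read(read, index, k, mode=mode, m=m)
        except ValueError as exc:
            logger.warning("skipping malformed read %r: %s", getattr(read, "id", "?"), exc)
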