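"""FASTA/FASTQ input and SAM output, plus index persistence.

Sequence parsing is delegated to Biopython's SeqIO; this module only
adapts records to the mapper's types, enforces the error contracts
(empty sequences, truncated FASTQ quartets) and handles the
global-to-per-sequence coordinate conversion on output.  SAM is
written as plain text; tests round-trip it through pysam.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from . import __version__
from .errors import ParseError
from .mapper import MappingReport, ReadRecord
from .reference_index import (
    GenomeIndex,
    GenomeSequence,
    place_sequences,
    reverse_complement,
)

_MAPQ = 255  # all mapping locations are reported; no ranking is meaningful
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_SECONDARY = 0x100


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Parse a (possibly multi-record, wrapped, CRLF) FASTA file.

    Sequences are upper-cased and placed contiguously in the global
    coordinate space in file order.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.read(1)
        if first and first != ">":
            raise ParseError(f"{path}:1: not a FASTA file (expected '>' header)")
    raw: list[tuple[str, str]] = []
    for record in SeqIO.parse(str(path), "fasta"):
        bases = str(record.seq).upper()
        if not bases:
            raise ParseError(f"{path}: record {record.id!r} has an empty sequence")
        raw.append((record.id, bases))
    return place_sequences(raw)


def _qual_string(record) -> str | None:
    phred = record.letter_annotations.get("phred_quality")
    if phred is None:
        return None
    return "".join(chr(q + 33) for q in phred)


def read_reads(path: str | Path) -> Iterator[ReadRecord]:
    """Stream reads from FASTQ or FASTA, auto-detected from the first byte."""
    path = Path(path)
    with path.open() as fh:
        first = fh.read(1)
    if not first:
        return
    if first == "@":
        fmt = "fastq"
    elif first == ">":
        fmt = "fasta"
    else:
        raise ParseError(f"{path}:1: unrecognized read format (expected '@' or '>')")
    index = 0
    try:
        for record in SeqIO.parse(str(path), fmt):
            index += 1
            yield ReadRecord(
                id=record.id, seq=str(record.seq).upper(), qual=_qual_string(record)
            )
    except ValueError as exc:
        raise ParseError(f"{path}: record {index + 1}: {exc}") from exc


def sam_header(index: GenomeIndex, program_args: str = "") -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for seq in index.sequences:
        lines.append(f"@SQ\tSN:{seq.name}\tLN:{len(seq)}")
    pg = f"@PG\tID:grammap\tPN:grammap\tVN:{__version__}"
    if program_args:
        pg += f"\tCL:{program_args}"
    lines.append(pg)
    return lines


def sam_records(index: GenomeIndex, report: MappingReport) -> list[str]:
    """SAM body lines for one read's report.

    All of a read's mappings share its name; the lowest-coordinate one
    is primary and the rest carry the secondary flag.  Reverse-strand
    records store the reverse-complemented sequence and reversed
    qualities, per SAM convention.  Suppressed (m-mapping) reads emit
    nothing.
    """
    read = report.read
    if report.suppressed_by_m:
        return []
    if report.unmapped or not report.results:
        qual = read.qual or "*"
        return [
            f"{read.id}\t{_FLAG_UNMAPPED}\t*\t0\t0\t*\t*\t0\t0\t{read.seq}\t{qual}"
        ]
    lines = []
    for i, res in enumerate(report.results):
        flag = 0
        if res.strand == "-":
            flag |= _FLAG_REVERSE
        if i > 0:
            flag |= _FLAG_SECONDARY
        ref_name, local = index.to_reference(res.start)
        seq = read.seq if res.strand == "+" else reverse_complement(read.seq)
        qual = read.qual or "*"
        if res.strand == "-" and read.qual:
            qual = read.qual[::-1]
        lines.append(
            "\t".join(
                [
                    read.id,
                    str(flag),
                    ref_name,
                    str(local + 1),  # SAM POS is 1-based
                    str(_MAPQ),
                    res.cigar,
                    "*",
                    "0",
                    "0",
                    seq,
                    qual,
                    f"NM:i:{res.distance}",
                ]
            )
        )
    return lines


def write_sam(
    index: GenomeIndex,
    reports: Iterable[MappingReport],
    path: str | Path,
    program_args: str = "",
) -> dict[str, int]:
    """Write a SAM file for a stream of reports; returns summary counters."""
    counters = {"reads": 0, "mapped": 0, "unmapped": 0, "suppressed": 0, "records": 0}
    with Path(path).open("w") as fh:
        for line in sam_header(index, program_args):
            fh.write(line + "\n")
        for report in reports:
            counters["reads"] += 1
            if report.suppressed_by_m:
                counters["suppressed"] += 1
            elif report.unmapped or not report.results:
                counters["unmapped"] += 1
            else:
                counters["mapped"] += 1
            for line in sam_records(index, report):
                fh.write(line + "\n")
                counters["records"] += 1
    return counters


# ---------------------------------------------------------------------------
# index persistence (compact JSON; deterministic and text-only)


def save_index(index: GenomeIndex, path: str | Path) -> None:
    payload = {
        "format": "grammap-index",
        "version": 1,
        "q": index.q,
        "sequences": [
            {"name": s.name, "offset": s.offset, "bases": s.bases}
            for s in index.sequences
        ],
        "lists": {str(code): locs for code, locs in sorted(index.lists.items())},
    }
    with Path(path).open("w") as fh:
        json.dump(payload, fh, separators=(",", ":"))


def load_index(path: str | Path) -> GenomeIndex:
    with Path(path).open() as fh:
        payload = json.load(fh)
    if payload.get("format") != "grammap-index":
        raise ParseError(f"{path}: not a grammap index file")
    sequences = [
        GenomeSequence(name=s["name"], bases=s["bases"], offset=s["offset"])
        for s in payload["sequences"]
    ]
    lists = {int(code): locs for code, locs in payload["lists"].items()}
    counts = {code: len(locs) for code, locs in lists.items()}
    return GenomeIndex(q=payload["q"], sequences=sequences, lists=lists, counts=counts)
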