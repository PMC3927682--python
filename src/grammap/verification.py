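"""Candidate verification: Hamming check or banded semi-global alignment.

A candidate is a hypothesized alignment start l.  Under Hamming
distance the read is compared position-wise against the window starting
at l.  Under edit distance the aligner consumes the whole read against
a genome window whose start is fixed and whose end is free, inside a
diagonal band of half-width k; the two-window heuristic first searches
[l, c+k] anchored at l (c = l + |r| - 1), and only if that yields
nothing searches [l-k, c] at every admissible start.  Alignments whose
traceback begins with reference deletions are re-anchored: the leading
deletions are stripped, the start advances past them and the distance
drops accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .candidates import CandidateLocation
from .errors import InvalidParameterError
from .reference_index import GenomeIndex

_INF = float("inf")


@dataclass(frozen=True)
class AlignmentResult:
    """A verified mapping location of a read."""

    ref_name: str
    start: int  # global 0-based alignment start
    strand: str  # "+" or "-"
    distance: int
    cigar: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvalidParameterError(f"invalid strand {self.strand!r}")

    @property
    def reference_span(self) -> int:
        """Number of reference bases consumed (CIGAR M + D)."""
        return sum(n for n, op in parse_cigar(self.cigar) if op in "MD=X")

    @property
    def read_span(self) -> int:
        """Number of read bases consumed (CIGAR M + I)."""
        return sum(n for n, op in parse_cigar(self.cigar) if op in "MI=X")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Split a CIGAR string into (length, op) pairs."""
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise InvalidParameterError(f"malformed CIGAR {cigar!r}")
            out.append((int(num), ch))
            num = ""
    if num:
        raise InvalidParameterError(f"malformed CIGAR {cigar!r}")
    return out


def _compress(ops: list[str]) -> str:
    out = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)


def hamming_verify(
    read: str, index: GenomeIndex, location: int, k: int, strand: str = "+"
) -> AlignmentResult | None:
    """Position-wise comparison of the read against the window at ``location``.

    Returns ``None`` when the window runs off the containing sequence or
    the mismatch count exceeds k.  The CIGAR is a single match run (the
    classic M dialect covers both match and mismatch).
    """
    window = index.fetch(location, len(read))
    if window is None:
        return None
    mismatches = 0
    for a, b in zip(read, window):
        if a != b:
            mismatches += 1
            if mismatches > k:
                return None
    ref_name, _ = index.to_reference(location)
    return AlignmentResult(
        ref_name=ref_name,
        start=location,
        strand=strand,
        distance=mismatches,
        cigar=f"{len(read)}M",
    )


# ---------------------------------------------------------------------------
# banded semi-global DP


def _banded_rows(read: str, window: str, k: int) -> list[list[float]]:
    """DP table D[i][j] = edit distance of read[:i] vs window[:j].

    Only cells with |i - j| <= k are computed; everything else stays
    +inf.  The window start is fixed (leading window bases cost a
    deletion each); the window end is left free by reading off the final
    row.
    """
    m, n = len(read), len(window)
    D = [[_INF] * (n + 1) for _ in range(m + 1)]
    for j in range(0, min(n, k) + 1):
        D[0][j] = float(j)
    for i in range(1, m + 1):
        lo = max(0, i - k)
        hi = min(n, i + k)
        if lo == 0:
            D[i][0] = float(i)
            lo = 1
        for j in range(lo, hi + 1):
            cost = 0 if read[i - 1] == window[j - 1] else 1
            best = D[i - 1][j - 1] + cost
            if D[i][j - 1] + 1 < best:
                best = D[i][j - 1] + 1
            if D[i - 1][j] + 1 < best:
                best = D[i - 1][j] + 1
            D[i][j] = best
    return D


def _traceback(
    read: str, window: str, D: list[list[float]], end: int
) -> list[str]:
    """Recover the alignment ops ending at cell (|read|, end).

    Ties prefer diagonal (M) over deletion (D, consumes window) over
    insertion (I, consumes read), for determinism.
    """
    ops: list[str] = []
    i, j = len(read), end
    while i > 0 or j > 0:
        here = D[i][j]
        if i > 0 and j > 0:
            cost = 0 if read[i - 1] == window[j - 1] else 1
            if D[i - 1][j - 1] + cost == here:
                ops.append("M")
                i -= 1
                j -= 1
                continue
        if j > 0 and D[i][j - 1] + 1 == here:
            ops.append("D")
            j -= 1
            continue
        if i > 0 and D[i - 1][j] + 1 == here:
            ops.append("I")
            i -= 1
            continue
        raise AssertionError("traceback lost the optimal path")
    ops.reverse()
    return ops


def _reanchor(
    cigar: str, distance: int
) -> tuple[str, int, int]:
    """Strip leading/trailing reference deletions from an alignment.

    A deletion run at either boundary merely shifts the alignment's
    anchor, so the distance drops with each stripped base.  Returns
    (cigar, distance, start_shift).
    """
    ops = parse_cigar(cigar)
    start_shift = 0
    if ops and ops[0][1] == "D":
        start_shift = ops[0][0]
        distance -= start_shift
        ops = ops[1:]
    if ops and ops[-1][1] == "D":
        distance -= ops[-1][0]
        ops = ops[:-1]
    return "".join(f"{n}{op}" for n, op in ops), distance, start_shift


def semiglobal_end_alignments(
    read: str, window: str, k: int
) -> list[tuple[int, int, str]]:
    """All anchored alignments of the whole read against window prefixes.

    Returns (distance, end_offset, cigar) for every window end offset
    whose final DP row value is at most k.  The window start is fixed:
    leading window bases skipped by the alignment appear as deletions
    and are charged (re-anchoring them is the caller's decision).
    """
    if k < 0:
        raise InvalidParameterError("k must be >= 0")
    m, n = len(read), len(window)
    if m == 0:
        return [(0, 0, "")]
    D = _banded_rows(read, window, k)
    out = []
    for end in range(max(0, m - k), min(n, m + k) + 1):
        if D[m][end] <= k:
            ops = _traceback(read, window, D, end)
            out.append((int(D[m][end]), end, _compress(ops)))
    return out


def banded_semiglobal(
    read: str, window: str, k: int
) -> tuple[int, int, str] | None:
    """Best semi-global alignment of the read from the window start.

    Returns (distance, end_offset, cigar) minimizing the distance (ties
    broken toward the smaller end offset), or ``None`` when no window
    prefix is within distance k.
    """
    if len(window) < 1:
        raise InvalidParameterError("window must be non-empty")
    hits = semiglobal_end_alignments(read, window, k)
    if not hits:
        return None
    return min(hits, key=lambda h: (h[0], h[1]))


def global_edit_distance(a: str, b: str) -> int:
    """Plain Levenshtein distance (both ends of both strings fixed)."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        ai = a[i - 1]
        for j in range(1, n + 1):
            cost = 0 if ai == b[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[n]


# ---------------------------------------------------------------------------
# two-window candidate verification


def verify_candidate(
    read: str,
    index: GenomeIndex,
    candidate: CandidateLocation,
    k: int,
    mode: str = "edit",
    strand: str = "+",
) -> list[AlignmentResult]:
    """Verify one candidate start, returning all mappings it yields.

    Hamming mode compares the window at l only.  Edit mode applies the
    two-window heuristic: the window [l, c+k] anchored at l first; if it
    yields nothing, the window [l-k, c] is searched at every admissible
    start (a full-read match ending at or before c cannot start after
    l+k).  Windows are clamped at the bounds of the sequence containing
    l.  Results are deduplicated by start, keeping the smallest distance
    (ties by lexicographically smallest CIGAR).
    """
    l = candidate.location
    seq = index.sequence_at(l)
    if seq is None:
        return []
    if mode == "hamming":
        res = hamming_verify(read, index, l, k, strand=strand)
        return [res] if res is not None else []
    if mode != "edit":
        raise InvalidParameterError(f"unknown mode {mode!r}")

    c = l + len(read) - 1
    best: dict[int, tuple[int, str]] = {}

    def record(start: int, dist: int, cigar: str) -> None:
        if not cigar:
            return
        old = best.get(start)
        if old is None or (dist, cigar) < old:
            best[start] = (dist, cigar)

    # window 1: [l, c+k], anchored at the candidate start
    w1 = index.fetch(l, len(read) + k, clamp=True)
    if w1:
        for dist, _end, cigar in semiglobal_end_alignments(read, w1, k):
            cigar, dist, shift = _reanchor(cigar, dist)
            record(l + shift, dist, cigar)

    if not best:
        # window 2: [l-k, c], every admissible start
        w2_lo = max(seq.offset, l - k)
        w2_end = min(c + 1, seq.end)  # exclusive
        for s in range(w2_lo, min(l + k, w2_end - 1) + 1):
            w = index.fetch(s, w2_end - s)
            if not w:
                continue
            for dist, _end, cigar in semiglobal_end_alignments(read, w, k):
                cigar, dist, shift = _reanchor(cigar, dist)
                record(s + shift, dist, cigar)

    ref_name = seq.name
    return [
        AlignmentResult(
            ref_name=ref_name, start=start, strand=strand, distance=dist, cigar=cigar
        )
        for start, (dist, cigar) in sorted(best.items())
    ]
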