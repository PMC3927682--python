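"""Synthetic genomes, error-bearing reads, and a full-sensitivity oracle.

The generator emulates the usual evaluation setup for all-mappers: a
random reference, reads sampled uniformly from both strands with a
configurable budget of substitutions, insertions and deletions, and a
recorded ground-truth origin for every read.  The oracle mapper scans
every window position exhaustively (the role a full-sensitive gold
standard plays when benchmarking real mappers) and is deliberately
implemented independently of the production filter/verify path: a
vectorized free-start DP over reversed strings yields, in one pass,
the anchored semi-global distance from *every* start position.

Base composition and error placement are uniform: the candidate
filters' guarantees are combinatorial, so no realistic error profile
is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .reference_index import (
    BASES,
    GenomeSequence,
    place_sequences,
    reverse_complement,
)

_BASE_ARR = np.frombuffer("ACGT".encode(), dtype=np.uint8)


@dataclass(frozen=True)
class SimulatedRead:
    """A sampled read plus its ground-truth origin and applied errors."""

    id: str
    seq: str
    qual: str | None
    ref_name: str
    origin_start: int  # 0-based, forward-strand coordinates
    strand: str
    substitutions: int
    insertions: int
    deletions: int

    @property
    def error_budget(self) -> int:
        return self.substitutions + self.insertions + self.deletions


def random_genome(
    length: int, n_sequences: int = 1, seed: int = 0
) -> list[GenomeSequence]:
    """Uniform i.i.d. ACGT sequences of total length ``length``."""
    if length < 1:
        raise InvalidParameterError("genome length must be >= 1")
    if n_sequences < 1 or n_sequences > length:
        raise InvalidParameterError("need 1 <= n_sequences <= length")
    rng = np.random.default_rng(seed)
    per = [length // n_sequences] * n_sequences
    per[-1] += length - sum(per)
    raw = []
    for i, n in enumerate(per):
        bases = rng.choice(_BASE_ARR, size=n).tobytes().decode()
        raw.append((f"sim{i + 1}", bases))
    return place_sequences(raw)


def _mutate(window: str, n_sub: int, n_ins: int, n_del: int, rng) -> str:
    """Apply deletions, then insertions, then substitutions to a window."""
    seq = list(window)
    if n_del:
        for pos in sorted(rng.choice(len(seq), size=n_del, replace=False), reverse=True):
            del seq[int(pos)]
    for _ in range(n_ins):
        pos = int(rng.integers(0, len(seq) + 1))
        seq.insert(pos, BASES[int(rng.integers(0, 4))])
    if n_sub:
        for pos in rng.choice(len(seq), size=n_sub, replace=False):
            pos = int(pos)
            choices = [b for b in BASES if b != seq[pos]]
            seq[pos] = choices[int(rng.integers(0, 3))]
    return "".join(seq)


def sample_reads(
    genome: list[GenomeSequence],
    n: int,
    read_length: int,
    max_sub: int = 0,
    max_ins: int = 0,
    max_del: int = 0,
    seed: int = 0,
    both_strands: bool = True,
) -> list[SimulatedRead]:
    """Sample ``n`` reads with uniformly drawn error counts within budgets.

    Origins are uniform over valid windows; the consumed reference span
    is ``read_length + deletions - insertions``.  Truth coordinates are
    always on the forward strand (matching the mapper's convention for
    reverse-strand hits).
    """
    if not genome:
        raise InvalidParameterError("genome must be non-empty")
    if max_del >= read_length:
        raise InvalidParameterError("deletion budget must be smaller than the read")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(s) for s in genome])
    reads: list[SimulatedRead] = []
    for i in range(n):
        n_sub = int(rng.integers(0, max_sub + 1))
        n_ins = int(rng.integers(0, max_ins + 1))
        n_del = int(rng.integers(0, max_del + 1))
        span = read_length + n_del - n_ins
        feasible = lengths - span
        ok = np.flatnonzero(feasible >= 0)
        if ok.size == 0:
            raise InvalidParameterError(
                f"no sequence can hold a window of {span} bases"
            )
        weights = (feasible[ok] + 1) / float((feasible[ok] + 1).sum())
        si = int(rng.choice(ok, p=weights))
        seq = genome[si]
        start = int(rng.integers(0, len(seq) - span + 1))
        window = seq.bases[start : start + span]
        mutated = _mutate(window, n_sub, n_ins, n_del, rng)
        strand = "+"
        if both_strands and rng.integers(0, 2) == 1:
            strand = "-"
            mutated = reverse_complement(mutated)
        reads.append(
            SimulatedRead(
                id=f"read{i + 1}",
                seq=mutated,
                qual="I" * len(mutated),
                ref_name=seq.name,
                origin_start=start,
                strand=strand,
                substitutions=n_sub,
                insertions=n_ins,
                deletions=n_del,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# exhaustive oracle


def _anchored_semiglobal_all_starts(read: str, text: str, band: int | None = None) -> np.ndarray:
    """dist[p] = min over e of edit_distance(read, text[p:e]) for every p.

    Computed as a single free-start (Sellers) DP over the reversed
    strings: with R = reversed read, T = reversed text and
    D[i][j] = min over s of edit_distance(R[:i], T[s:j]),
    the final row at column len(text) - p is exactly the anchored
    semi-global distance from start p.  The column scan is vectorized;
    the horizontal (deletion) dependency is resolved with the classic
    prefix-minimum trick on tmp[j] - j.
    """
    R = np.frombuffer(read[::-1].encode(), dtype=np.uint8)
    T = np.frombuffer(text[::-1].encode(), dtype=np.uint8)
    n = T.size
    row = np.zeros(n + 1, dtype=np.float64)  # free start: D[0][j] = 0
    for i in range(1, R.size + 1):
        cost = (T != R[i - 1]).astype(np.float64)
        tmp = np.empty(n + 1)
        tmp[0] = i  # only vertical moves in column 0
        tmp[1:] = np.minimum(row[:-1] + cost, row[1:] + 1.0)
        # horizontal closure: D[i][j] = min_{j' <= j} tmp[j'] + (j - j')
        shifted = np.minimum.accumulate(tmp - np.arange(n + 1))
        row = shifted + np.arange(n + 1)
    return row[::-1][: n + 1]  # index p -> distance from start p


def oracle_map(
    read: str,
    genome: list[GenomeSequence],
    k: int,
    mode: str = "edit",
) -> list[tuple[int, str, int]]:
    """Every mapping location of the read within distance k, both strands.

    Returns (global start, strand, distance) triples, sorted.  Hamming
    mode counts mismatches at every window position; edit mode reports
    every start from which a semi-global alignment of the whole read
    achieves distance <= k.  Complete by construction; the production
    mapper is validated against it.
    """
    if mode not in ("hamming", "edit"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    out: list[tuple[int, str, int]] = []
    for seq in genome:
        text = seq.bases
        arr = np.frombuffer(text.encode(), dtype=np.uint8)
        for strand in "+-":
            oriented = read if strand == "+" else reverse_complement(read)
            m = len(oriented)
            if mode == "hamming":
                if m > len(text):
                    continue
                r = np.frombuffer(oriented.encode(), dtype=np.uint8)
                n_win = len(text) - m + 1
                mism = np.zeros(n_win, dtype=np.int64)
                for i in range(m):
                    mism += arr[i : i + n_win] != r[i]
                for p in np.flatnonzero(mism <= k):
                    out.append((seq.offset + int(p), strand, int(mism[p])))
            else:
                dist = _anchored_semiglobal_all_starts(oriented, text)
                # a start needs at least m - k remaining bases
                limit = len(text) - max(1, m - k) + 1
                for p in range(max(0, limit)):
                    if dist[p] <= k:
                        out.append((seq.offset + p, strand, int(dist[p])))
    out.sort()
    return out
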