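"""Frequency-optimal selection of non-overlapping prefix q-grams.

A genome subsequence within Hamming distance k of a read must contain,
unmodified and at the same offsets, all but at most k of any set of
non-overlapping read grams.  Candidate generation therefore wants the
c = k+1 (union filter) or c = k+2 (additional-prefix filter)
non-overlapping grams whose inverted lists are shortest in aggregate.
The dynamic program below finds that optimum exactly; the classic
k*q+1 overlapping prefix scheme is kept as a baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError, NotEnoughGramsError
from .reference_index import GenomeIndex, extract_overlapping_grams

#: effective list length of a gram containing N: never selected if avoidable
_INF = math.inf


@dataclass(frozen=True)
class PrefixPick:
    """One selected gram: its read offset, bases and inverted-list length."""

    offset: int
    gram: str
    list_length: int


@dataclass(frozen=True)
class PrefixSelection:
    """The chosen non-overlapping grams of a read and their summed frequency."""

    picks: tuple[PrefixPick, ...]
    total: int

    def __post_init__(self) -> None:
        offsets = [p.offset for p in self.picks]
        if any(b - a < 1 for a, b in zip(offsets, offsets[1:])):
            raise InvalidParameterError("selected offsets must be strictly increasing")


def max_nonoverlapping_grams(read_length: int, q: int) -> int:
    """Maximum number of mutually non-overlapping q-grams in a read.

    floor(|r| / q); e.g. a 100bp read holds 9 non-overlapping 11-grams,
    so the two-vote filter is available up to k = 7.
    """
    if q <= 0:
        raise InvalidParameterError(f"gram length q must be >= 1, got {q}")
    if read_length < 0:
        raise InvalidParameterError("read length must be >= 0")
    return read_length // q


def _list_lengths(read: str, index: GenomeIndex) -> list[float]:
    """Inverted-list length of each overlapping gram; N-grams count as inf."""
    q = index.q
    out: list[float] = []
    for _, gram in extract_overlapping_grams(read, q):
        out.append(_INF if "N" in gram else index.count(gram))
    return out


def select_prefix_grams(read: str, index: GenomeIndex, count: int) -> PrefixSelection:
    """Select ``count`` non-overlapping grams minimizing total list length.

    Dynamic program over M(i, j), the minimum summed list length of i
    non-overlapping grams whose i-th member is gram number j + (i-1)*q
    or earlier (1-based gram numbering over the |r|-q+1 overlapping
    grams).  M(0, j) = 0, M(i, 0) = inf, and

        M(i, j) = min( M(i, j-1),  M(i-1, j) + len[j + (i-1)*q] )

    The goal cell is M(count, |G(r)| - (count-1)*q); traceback recovers
    the offsets, preferring the leftmost placement on ties.
    """
    if count < 1:
        raise InvalidParameterError("count must be >= 1")
    q = index.q
    n_grams = len(read) - q + 1
    if max_nonoverlapping_grams(len(read), q) < count:
        raise NotEnoughGramsError(
            f"read of length {len(read)} holds fewer than {count} non-overlapping {q}-grams"
        )
    lengths = _list_lengths(read, index)  # 0-based: lengths[n-1] is gram n
    J = n_grams - (count - 1) * q
    # M[i][j]; gram number for the take-branch at (i, j) is j + (i-1)*q
    M = [[0.0] * (J + 1) for _ in range(count + 1)]
    for i in range(1, count + 1):
        M[i][0] = _INF
        for j in range(1, J + 1):
            take = M[i - 1][j] + lengths[j + (i - 1) * q - 1]
            M[i][j] = min(M[i][j - 1], take)
    total = M[count][J]
    if math.isinf(total):
        raise NotEnoughGramsError(
            "every feasible selection includes a gram containing N"
        )
    # traceback, preferring smaller j (leftmost gram placement) on ties
    picks: list[PrefixPick] = []
    i, j = count, J
    while i > 0:
        if j > 1 and M[i][j] == M[i][j - 1]:
            j -= 1
            continue
        n = j + (i - 1) * q  # 1-based gram number taken as the i-th pick
        offset = n - 1
        gram = read[offset : offset + q]
        picks.append(PrefixPick(offset=offset, gram=gram, list_length=int(lengths[offset])))
        i -= 1
    picks.reverse()
    return PrefixSelection(picks=tuple(picks), total=int(total))


def classic_prefix_grams(
    read: str, index: GenomeIndex, k: int
) -> list[tuple[int, str]]:
    """The classic prefix filter's gram set: the k*q+1 rarest overlapping grams.

    Any window within Hamming distance k must retain at least one of
    them, so the union of their normalized lists is a lossless candidate
    superset.  Ties in frequency break toward the smaller read offset.
    """
    if k < 0:
        raise InvalidParameterError("k must be >= 0")
    q = index.q
    grams = extract_overlapping_grams(read, q)
    need = k * q + 1
    if len(grams) < need:
        raise NotEnoughGramsError(
            f"read has {len(grams)} overlapping grams, fewer than k*q+1 = {need}"
        )
    lengths = _list_lengths(read, index)
    order = sorted(range(len(grams)), key=lambda n: (lengths[n], n))
    return [grams[n] for n in sorted(order[:need])]
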