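"""Candidate alignment-start generation from normalized inverted lists.

Three filters, in increasing selectivity:

* ``naive_count_filter`` — scan all |G(r)| normalized lists and keep
  locations occurring at least T = |r|-q+1-k*q times.  Exact but slow;
  kept as the reference oracle for the Hamming case.
* ``prefix_union_candidates`` — the pigeonhole union of k+1
  non-overlapping gram lists (at most k substitutions can destroy at
  most k of them, so a true match keeps at least one).
* ``additional_prefix_candidates`` — select k+2 non-overlapping grams
  and keep locations voted for by at least two of them: with at most k
  errors, at least two grams survive intact.  Equivalent to the union
  of pairwise intersections of the k+2 lists, but computed by a single
  multiway merge.  Under edit distance, indels between two surviving
  grams shift their normalized locations apart by at most k, so two
  single-vote locations from different gram lists within k of each
  other are both admitted ("singleton pair").
"""

from __future__ import annotations

import heapq
from collections import Counter
from dataclasses import dataclass, field

from .errors import InvalidParameterError
from .prefix_selection import PrefixSelection
from .reference_index import GenomeIndex, extract_overlapping_grams, normalize_list


@dataclass(frozen=True)
class CandidateLocation:
    """A hypothesized alignment start with its voting provenance."""

    location: int
    votes: int
    singleton_pair: bool = False
    #: read offsets of the gram occurrences that voted for this location
    sources: tuple[int, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.votes < 1:
            raise InvalidParameterError("a candidate needs at least one vote")
        if self.singleton_pair and self.votes != 1:
            raise InvalidParameterError("singleton-pair candidates have exactly one vote")


def count_threshold(read_length: int, q: int, k: int) -> int:
    """Count-filtering lower bound T = |r| - q + 1 - k*q.

    A window within Hamming distance k of the read shares at least T of
    its overlapping grams (each substitution destroys at most q of
    them).  May be <= 0, in which case the count filter is vacuous.
    """
    if read_length < q:
        raise InvalidParameterError("read shorter than the gram length")
    return read_length - q + 1 - k * q


def filter_by_count(
    normalized_lists: list[list[int]], threshold: int
) -> list[CandidateLocation]:
    """Locations occurring in at least ``threshold`` of the given lists.

    Each list contributes at most one occurrence per location (lists are
    strictly increasing by construction); repeated grams of a read enter
    as separate lists and therefore vote separately.
    """
    if threshold <= 0:
        raise InvalidParameterError(
            f"count threshold {threshold} is vacuous; the filter is undefined"
        )
    counts: Counter[int] = Counter()
    for lst in normalized_lists:
        counts.update(lst)
    return [
        CandidateLocation(location=loc, votes=n)
        for loc, n in sorted(counts.items())
        if n >= threshold
    ]


def naive_count_filter(
    read: str, index: GenomeIndex, k: int
) -> list[CandidateLocation]:
    """Count filtering over all |G(r)| normalized lists (reference oracle)."""
    threshold = count_threshold(len(read), index.q, k)
    lists = [
        normalize_list(index.lookup(gram), offset)
        for offset, gram in extract_overlapping_grams(read, index.q)
    ]
    return filter_by_count(lists, threshold)


def _normalized_pick_lists(
    selection: PrefixSelection, index: GenomeIndex
) -> list[tuple[int, list[int]]]:
    return [
        (pick.offset, normalize_list(index.lookup(pick.gram), pick.offset))
        for pick in selection.picks
    ]


def prefix_union_candidates(
    selection: PrefixSelection, index: GenomeIndex
) -> list[CandidateLocation]:
    """Union of the normalized lists of k+1 non-overlapping grams.

    The lossless fallback used when a read cannot supply k+2
    non-overlapping grams.
    """
    votes: dict[int, list[int]] = {}
    for offset, lst in _normalized_pick_lists(selection, index):
        for loc in lst:
            votes.setdefault(loc, []).append(offset)
    return [
        CandidateLocation(location=loc, votes=len(srcs), sources=tuple(srcs))
        for loc, srcs in sorted(votes.items())
    ]


def additional_prefix_candidates(
    selection: PrefixSelection,
    index: GenomeIndex,
    k: int,
    mode: str = "hamming",
) -> list[CandidateLocation]:
    """Two-vote filter over k+2 non-overlapping gram lists.

    A single ascending multiway merge accumulates, per location, the
    gram occurrences that voted for it; locations with >= 2 votes are
    candidates.  In ``edit`` mode, pairs of single-vote locations from
    different gram occurrences whose distance is at most k are both
    admitted as singleton-pair candidates (indels between two intact
    grams displace their normalized locations by at most k).
    """
    if mode not in ("hamming", "edit"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    tagged = _normalized_pick_lists(selection, index)
    merged = heapq.merge(*([(loc, offset) for loc in lst] for offset, lst in tagged))
    out: list[CandidateLocation] = []
    singles: list[tuple[int, int]] = []  # (location, source offset)
    run_loc: int | None = None
    run_sources: list[int] = []

    def flush() -> None:
        if run_loc is None:
            return
        if len(run_sources) >= 2:
            out.append(
                CandidateLocation(
                    location=run_loc,
                    votes=len(run_sources),
                    sources=tuple(sorted(run_sources)),
                )
            )
        else:
            singles.append((run_loc, run_sources[0]))

    for loc, source in merged:
        if loc != run_loc:
            flush()
            run_loc, run_sources = loc, [source]
        else:
            run_sources.append(source)
    flush()

    if mode == "edit" and singles:
        admitted = set()
        for i, (loc_a, src_a) in enumerate(singles):
            for loc_b, src_b in singles[i + 1 :]:
                if loc_b - loc_a > k:
                    break
                if src_a != src_b:
                    admitted.add((loc_a, src_a))
                    admitted.add((loc_b, src_b))
        for loc, src in sorted(admitted):
            out.append(
                CandidateLocation(
                    location=loc, votes=1, singleton_pair=True, sources=(src,)
                )
            )
    out.sort(key=lambda c: c.location)
    return out


def subset_count(k: int) -> int:
    """Number of (k+1)-subsets of k+2 grams: k+2.

    Documents why two votes suffice: a true match appears in the union
    candidate set of every (k+1)-subset, i.e. in their intersection,
    which equals the union of pairwise intersections.
    """
    if k < 0:
        raise InvalidParameterError("k must be >= 0")
    return k + 2
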