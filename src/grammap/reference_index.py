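"""Overlapping q-gram inverted index over a reference genome.

The index maps every length-q substring (gram) of the reference to the
sorted list of genome positions where it occurs, in a single global
coordinate space obtained by concatenating all sequences.  Inverted
lists of a read's grams, shifted by the gram's offset in the read
("normalized"), vote for hypothesized alignment start positions; the
candidate filters in :mod:`grammap.candidates` operate on those lists.

Coordinates are 0-based half-open throughout; SAM emission converts to
1-based at the very end.  Grams are stored 2-bit-packed (A=0, C=1, G=2,
T=3); windows containing N are not indexed, and a read gram containing
N simply has an empty inverted list.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from .errors import InvalidParameterError

#: canonical 4-letter alphabet; N is tolerated in input but never indexed
BASES = "ACGT"

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_DECODE = dict(enumerate(BASES))

VALID_CHARS = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(s: str) -> str:
    """Reverse complement over {A, C, G, T, N}."""
    return s.translate(_COMPLEMENT)[::-1]


def encode_gram(gram: str) -> int:
    """Pack an ACGT string into a 2-bit-per-base integer.

    Raises :class:`InvalidParameterError` if the gram contains any
    character outside {A, C, G, T} (including N).
    """
    code = 0
    try:
        for base in gram:
            code = (code << 2) | _CODE[base]
    except KeyError as exc:
        raise InvalidParameterError(
            f"gram contains non-ACGT character {exc.args[0]!r}"
        ) from None
    return code


def decode_gram(code: int, q: int) -> str:
    """Inverse of :func:`encode_gram` for a gram of length ``q``."""
    out = []
    for _ in range(q):
        out.append(_DECODE[code & 3])
        code >>= 2
    return "".join(reversed(out))


def extract_overlapping_grams(s: str, q: int) -> list[tuple[int, str]]:
    """All overlapping q-grams of ``s`` as ``(offset, gram)`` pairs.

    Duplicate grams are retained as distinct entries (an ordered
    multiset): a gram occurring at two read offsets contributes two
    separate inverted lists downstream.

    >>> extract_overlapping_grams("ACCTACCT", 3)[:2]
    [(0, 'ACC'), (1, 'CCT')]
    """
    if q <= 0:
        raise InvalidParameterError(f"gram length q must be >= 1, got {q}")
    return [(i, s[i : i + q]) for i in range(len(s) - q + 1)]


@dataclass(frozen=True)
class GenomeSequence:
    """One reference sequence placed in the global coordinate space."""

    name: str
    bases: str
    offset: int = 0

    def __post_init__(self) -> None:
        bad = set(self.bases) - VALID_CHARS
        if bad:
            raise InvalidParameterError(
                f"sequence {self.name!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def end(self) -> int:
        """Global position one past the last base."""
        return self.offset + len(self.bases)


def place_sequences(raw: list[tuple[str, str]]) -> list[GenomeSequence]:
    """Assign contiguous global offsets to named sequences."""
    out = []
    offset = 0
    for name, bases in raw:
        seq = GenomeSequence(name=name, bases=bases.upper(), offset=offset)
        out.append(seq)
        offset = seq.end
    return out


@dataclass
class GenomeIndex:
    """Reference sequences plus their overlapping q-gram inverted index.

    ``lists`` maps the packed gram code to a strictly increasing list of
    global start positions whose q-length window lies inside a single
    sequence and contains no N.  ``counts`` caches the list lengths
    (the DP gram selection sorts on them heavily).
    """

    q: int
    sequences: list[GenomeSequence]
    lists: dict[int, list[int]] = field(default_factory=dict)
    counts: dict[int, int] = field(default_factory=dict)

    # -- coordinate helpers -------------------------------------------------

    @property
    def total_length(self) -> int:
        return self.sequences[-1].end if self.sequences else 0

    def sequence_at(self, location: int) -> GenomeSequence | None:
        """The sequence containing global position ``location``."""
        if location < 0 or location >= self.total_length:
            return None
        starts = [s.offset for s in self.sequences]
        i = bisect_right(starts, location) - 1
        return self.sequences[i]

    def fetch(self, start: int, length: int, clamp: bool = False) -> str | None:
        """Bases of the window ``[start, start+length)``.

        Returns ``None`` if the window does not lie within a single
        sequence, unless ``clamp`` is set, in which case the window is
        truncated at the containing sequence's bounds.
        """
        seq = self.sequence_at(start)
        if seq is None:
            return None
        end = start + length
        if end > seq.end:
            if not clamp:
                return None
            end = seq.end
        local = start - seq.offset
        return seq.bases[local : local + (end - start)]

    def to_reference(self, location: int) -> tuple[str, int]:
        """Map a global position to ``(sequence name, local 0-based pos)``."""
        seq = self.sequence_at(location)
        if seq is None:
            raise InvalidParameterError(f"location {location} outside the genome")
        return seq.name, location - seq.offset

    # -- index queries ------------------------------------------------------

    def lookup(self, gram: str) -> list[int]:
        """Inverted list I(g): sorted global positions of ``gram``.

        Absent grams (including grams containing N, which are never
        indexed) yield the empty list.
        """
        if len(gram) != self.q:
            raise InvalidParameterError(
                f"gram length {len(gram)} does not match index q={self.q}"
            )
        if "N" in gram:
            return []
        return self.lists.get(encode_gram(gram), [])

    def count(self, gram: str) -> int:
        """Length of the inverted list of ``gram`` (its genome frequency)."""
        if len(gram) != self.q:
            raise InvalidParameterError(
                f"gram length {len(gram)} does not match index q={self.q}"
            )
        if "N" in gram:
            return 0
        return self.counts.get(encode_gram(gram), 0)


def build_index(sequences: list[GenomeSequence], q: int) -> GenomeIndex:
    """Build the overlapping q-gram inverted index of a genome.

    A rolling 2-bit code is slid over each sequence; windows overlapping
    an N (or a sequence boundary) are skipped.  Scanning sequences in
    offset order makes every inverted list sorted by construction.
    """
    if q <= 0:
        raise InvalidParameterError(f"gram length q must be >= 1, got {q}")
    seqs = sorted(sequences, key=lambda s: s.offset)
    for prev, cur in zip(seqs, seqs[1:]):
        if cur.offset < prev.end:
            raise InvalidParameterError(
                f"sequences {prev.name!r} and {cur.name!r} overlap in global coordinates"
            )
    lists: dict[int, list[int]] = {}
    mask = (1 << (2 * q)) - 1
    for seq in seqs:
        code = 0
        valid = 0  # bases accumulated since the last N
        for i, base in enumerate(seq.bases):
            b = _CODE.get(base)
            if b is None:  # N: restart the window
                valid = 0
                code = 0
                continue
            code = ((code << 2) | b) & mask
            valid += 1
            if valid >= q:
                start = seq.offset + i - q + 1
                lists.setdefault(code, []).append(start)
    counts = {g: len(l) for g, l in lists.items()}
    return GenomeIndex(q=q, sequences=seqs, lists=lists, counts=counts)


def normalize_list(locations: list[int], read_offset: int) -> list[int]:
    """Shift an inverted list by a gram's read offset: I^n(g) = I(g) - l.

    Each element becomes a hypothesized alignment *start* of the whole
    read.  Entries that would become negative are dropped: no full-length
    read window exists there (indel-shifted starts near the origin are
    recovered later by verification, which clamps windows at 0).
    """
    if read_offset < 0:
        raise InvalidParameterError("read offset must be >= 0")
    return [l - read_offset for l in locations if l >= read_offset]
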