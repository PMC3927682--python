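# Methods

## Problem and model

grammap solves the all-mapping problem: report every genome location where a
read aligns within a distance threshold *k*, under either Hamming distance
(substitutions only) or unit-cost edit distance. The design is
filter-and-verify: a combinatorial candidate filter built on a *q*-gram
inverted index bounds the set of plausible alignment starts, and a banded
alignment verifies each survivor.

All internal coordinates are 0-based, half-open, in a single global space
formed by concatenating the reference sequences; SAM output converts to
1-based per-sequence positions at emission. Candidates whose read window
would straddle two sequences are rejected during verification (windows are
clamped to the sequence containing the candidate).

## Candidate filters

**Count filter (oracle).** Two length-|r| strings within Hamming distance
*k* share at least T = |r| − q + 1 − k·q of their overlapping grams, since
one substitution destroys at most *q* of them. Scanning all |G(r)|
normalized lists and keeping locations with multiplicity ≥ T is exact but
linear in total list length; it is retained as a reference oracle and
refuses to run when T ≤ 0.

**k+1 union.** Of k+1 *non-overlapping* grams, at most *k* can be destroyed
by *k* substitutions, so the union of their normalized lists is lossless.
Used as the fallback when a read is too short for k+2 grams.

**k+2 two-vote filter.** With k+2 non-overlapping grams at least two survive
intact, so only locations appearing on ≥ 2 normalized lists are kept. The
candidate set equals the union of pairwise intersections of the k+2 lists
and is computed by a single ascending multiway merge with a per-location
vote accumulator. Votes are counted over gram *occurrences* (distinct read
offsets): a gram string repeated in the read enters as separate lists and
votes separately, consistent with treating G(r) as an ordered multiset.

**Indel (singleton-pair) relaxation.** Under edit distance, indels between
two intact grams displace their normalized votes from each other by at most
the total indel count ≤ k. Two locations with exactly one vote each, from
different gram occurrences, at distance ≤ k, are therefore both admitted as
candidates. Pairs are evaluated independently (no transitive chaining
beyond what pairwise marking implies); a location admitted both by votes
and by a pair keeps its ≥ 2 votes and is not flagged.

## Gram selection

The c grams (c = k+1 or k+2) are chosen to minimize the summed
inverted-list lengths over all non-overlapping placements, by the dynamic
program

    M(i, j) = min( M(i, j−1),  M(i−1, j) + len[j + (i−1)·q] ),

with M(0, j) = 0, M(i, 0) = ∞ and goal M(c, |G(r)| − (c−1)·q), where
len[n] is the list length of the n-th overlapping gram. The recurrence is
count-agnostic, so one implementation serves both c = k+1 and c = k+2.
Traceback prefers the leftmost placement on ties, making selection
deterministic. Read grams containing N get infinite effective length: they
are never selected when avoidable, and if every feasible selection needs
one, selection fails over to the next weaker filter path.

The classic prefix scheme (the k·q+1 rarest *overlapping* grams, ties to
the smaller offset) is kept as a baseline; its union is also a lossless
Hamming candidate set.

## Verification

**Hamming.** Direct position-wise comparison at the candidate start with
early abandon past *k*; CIGAR is a single M run (M covers match and
mismatch; the =/X dialect is deliberately not used).

**Edit.** The aligner computes D[i][j] = edit distance of read[:i] vs
window[:j] inside a diagonal band |i − j| ≤ k; the window start is fixed
(leading window bases cost a deletion each) and the window end is free:
every final-row cell ≤ k yields an alignment, recovered by traceback with
deterministic tie-breaking (diagonal over deletion over insertion).
Alignments whose CIGAR begins or ends with deletions are re-anchored: the
boundary deletions are stripped, the start shifts past them, and the
distance drops accordingly, so no emitted record starts or ends with D.

For a candidate *l* with c = l + |r| − 1, verification searches the window
[l, c+k] anchored at *l* first; only if it yields nothing, the window
[l−k, c] is searched at every start s ∈ [l−k, l+k] (a full-read match
ending at or before c cannot start after l+k, so this enumerates exactly
the matches inside the second window). Results are deduplicated by start,
keeping the smallest distance and, on ties, the lexicographically smallest
CIGAR.

The anchored-first policy is what makes the deletion-shifted worked
instance recoverable: a free-start first window would find an
insertion-variant inside [l, c+k] and stop before the second window could
reveal the earlier start. The price is the documented heuristic loss:
mappings that start before *l* and end after *c* escape both windows, and
when the first window succeeds the second is skipped entirely, so
additional co-located variants can be missed. The test suite measures this
loss against a brute-force oracle and certifies every miss mechanically
(each one must be either a shift-variant of a reported alignment or
unreachable in every window the policy searched); it does not assume the
loss away.

## Mapper orchestration

Both orientations of each read are mapped (reverse complement with the SAM
reverse flag; reverse-strand coordinates are reported on the forward
strand). The filter path is gated per read by ⌊|r|/q⌋ ≥ k+2 / ≥ k+1,
evaluated for each read rather than once for the first: strictly safer for
variable-length input at negligible cost. Reads too short for even k+1
grams fall back to verifying every genome position (safe, unfiltered);
reads shorter than *q* are reported unmapped with a warning. Results merge
across strands, deduplicated by (reference, start, strand) keeping the
smallest distance. In m-mapping mode a read with more than *m* distinct
locations is suppressed entirely (no SAM record; counted in the log
summary). MAPQ is fixed at 255: an all-mapper reports, it does not rank.

`map_all` guarantees worker-count-independent output; execution is
sequential, since reads are independent and the contract is determinism,
not throughput.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| q | 11 | gram length; 4^q hash-table size vs. list length trade-off. 11 suits gigabase references and 100 bp reads (9 non-overlapping grams, so k ≤ 7 keeps the two-vote path). Desk-scale experiments on ~10²–10⁵ bp references use q = 3–7 so lists are non-trivial. |
| k | 2 (CLI) | distance threshold, Hamming or edit |
| mode | edit | hamming restricts to substitutions and skips windowed alignment |
| m | off | m-mapping cap on distinct locations per read |
| band | = k | half-width of the alignment band; with the two windows it covers every start shift the filter can produce |

## Synthetic data and the oracle

`random_genome` draws uniform i.i.d. ACGT bases; `sample_reads` draws
origins uniformly over valid windows and both strands, error counts
uniformly within the configured substitution/insertion/deletion budgets,
and records the exact truth (forward-strand origin, strand, counts). The
generator emulates the combinatorial structure the filters depend on —
planted matches at known distances — and deliberately not the statistics of
real data: no base-composition bias, no repeat families beyond chance, no
quality-correlated errors, no N runs. Passing tests therefore demonstrate
the filter guarantees and alignment correctness, not performance on real
genomes, where long repeat-induced inverted lists dominate running time.

`oracle_map` is the full-sensitivity gold standard: in Hamming mode a
vectorized mismatch count over every window; in edit mode the anchored
semi-global distance from *every* start, obtained in one pass as a
free-start (Sellers) DP over the reversed read and reversed reference —
the final row of that DP, read backwards, is exactly the per-start anchored
distance. It shares no code with the production aligner and is additionally
cross-checked against edlib in the tests. Note its start semantics charge
leading deletions, so it counts shift-variant starts that the mapper
canonicalizes away; the end-to-end tests treat those as equivalent variants
of a reported locus.

## Numerical and degenerate-input choices

* Grams are 2-bit packed integers; windows containing N are not indexed,
  and an N-containing read gram has an empty list.
* Normalized locations that would be negative are dropped (no full-length
  window exists there); verification clamps windows at sequence bounds.
* All randomness is seeded; identical flags and seeds give byte-identical
  output.
* Problem sizes in the test suite (genomes 1–100 kb, reads 30–100 bp,
  200–1000 reads, k ≤ 3) were chosen so every brute-force oracle remains
  exhaustive at desk scale while still exercising multi-candidate and
  multi-strand paths.

## Known limitations

* The two-window heuristic can miss mappings that start before *l* and end
  after *c*, and — because the second window only runs when the first is
  empty — co-located variants of a found mapping; both cases are measured
  in the suite and are rare under uniform simulation.
* No paired-end logic, no affine gaps, no quality-aware scoring, no BAM.
* The whole index lives in memory; no compressed or disk-resident variant.
* Repetitive references can make the unfiltered fallback path (reads with
  fewer than k+1 grams) very slow; it exists for safety, not speed.
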