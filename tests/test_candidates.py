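"""Candidate-generation filters: count, union, and two-vote merge."""

import itertools

import numpy as np
import pytest

import grammap as gm
from grammap.errors import InvalidParameterError

from conftest import brute_hamming_starts


@pytest.mark.parametrize(
    "length,q,k,expected", [(17, 5, 2, 3), (100, 11, 0, 90), (12, 5, 2, -2)]
)
def test_count_threshold_formula(length, q, k, expected):
    assert gm.count_threshold(length, q, k) == expected


class TestFilterByCount:
    def test_printed_normalized_lists_instance(self):
        """Three normalized lists; only the location shared by all three survives T=3."""
        lists = [[105, 118], [105], [92, 105]]
        cands = gm.filter_by_count(lists, 3)
        assert [(c.location, c.votes) for c in cands] == [(105, 3)]

    def test_vacuous_threshold_refused(self):
        with pytest.raises(InvalidParameterError):
            gm.filter_by_count([[1]], 0)


class TestNaiveCountFilter:
    def test_exact_read_recovers_its_origin(self, small_genome, small_index):
        text = small_genome[0].bases
        read = text[700:730]
        cands = gm.naive_count_filter(read, small_index, 0)
        locs = {c.location for c in cands}
        assert locs == set(brute_hamming_starts(read, text, 0))

    def test_agrees_with_direct_multiplicity_count(self, small_index):
        rng = np.random.default_rng(5)
        bases = "ACGT"
        read = "".join(bases[i] for i in rng.integers(0, 4, size=25))
        k = 1
        T = gm.count_threshold(len(read), small_index.q, k)
        counts = {}
        for off, g in gm.extract_overlapping_grams(read, small_index.q):
            for loc in gm.normalize_list(small_index.lookup(g), off):
                counts[loc] = counts.get(loc, 0) + 1
        expected = {loc for loc, n in counts.items() if n >= T}
        got = {c.location for c in gm.naive_count_filter(read, small_index, k)}
        assert got == expected


class TestPrefixUnionCandidates:
    def test_k0_is_the_single_normalized_list(self, small_index):
        read = small_index.sequences[0].bases[40:70]
        sel = gm.select_prefix_grams(read, small_index, 1)
        cands = gm.prefix_union_candidates(sel, small_index)
        pick = sel.picks[0]
        assert [c.location for c in cands] == gm.normalize_list(
            small_index.lookup(pick.gram), pick.offset
        )

    def test_covers_all_hamming_matches(self, small_genome, small_index):
        text = small_genome[0].bases
        rng = np.random.default_rng(8)
        bases = "ACGT"
        for trial in range(25):
            k = int(rng.integers(0, 3))
            start = int(rng.integers(0, len(text) - 36))
            read = list(text[start : start + 36])
            for pos in rng.choice(36, size=k, replace=False):
                read[pos] = bases[(bases.index(read[pos]) + 1) % 4]
            read = "".join(read)
            sel = gm.select_prefix_grams(read, small_index, k + 1)
            locs = {c.location for c in gm.prefix_union_candidates(sel, small_index)}
            assert set(brute_hamming_starts(read, text, k)) <= locs

    def test_disjoint_lists_union_size(self):
        idx = gm.build_index(gm.place_sequences([("chr", "ACGTACGTTTTTTTTT")]), 4)
        sel = gm.PrefixSelection(
            picks=(
                gm.PrefixPick(0, "ACGT", idx.count("ACGT")),
                gm.PrefixPick(4, "TTTT", idx.count("TTTT")),
            ),
            total=idx.count("ACGT") + idx.count("TTTT"),
        )
        cands = gm.prefix_union_candidates(sel, idx)
        a = len(gm.normalize_list(idx.lookup("ACGT"), 0))
        b = len(gm.normalize_list(idx.lookup("TTTT"), 4))
        assert sum(c.votes for c in cands) == a + b


def _random_selection(rng, index, text, count, k_sub):
    """A read sampled from the genome with k_sub substitutions, plus its selection."""
    bases = "ACGT"
    length = int(rng.integers(count * index.q, count * index.q + 12))
    start = int(rng.integers(0, len(text) - length))
    read = list(text[start : start + length])
    for pos in rng.choice(length, size=k_sub, replace=False):
        read[pos] = bases[(bases.index(read[pos]) + 1) % 4]
    read = "".join(read)
    return read, gm.select_prefix_grams(read, index, count)


class TestAdditionalPrefixCandidates:
    def test_indel_singleton_pair_instance(self):
        """Two single-vote locations one apart are both admitted in edit mode."""
        genome = gm.place_sequences([("g", "CCAGTAATGCTGTTG")])
        idx = gm.build_index(genome, 3)
        sel = gm.PrefixSelection(
            picks=(
                gm.PrefixPick(0, "AGT", idx.count("AGT")),
                gm.PrefixPick(4, "ATC", idx.count("ATC")),
                gm.PrefixPick(9, "TTG", idx.count("TTG")),
            ),
            total=2,
        )
        edit = gm.additional_prefix_candidates(sel, idx, 1, mode="edit")
        assert [(c.location, c.votes, c.singleton_pair) for c in edit] == [
            (2, 1, True),
            (3, 1, True),
        ]
        # under Hamming the same instance yields nothing: no two-list location
        assert gm.additional_prefix_candidates(sel, idx, 1, mode="hamming") == []

    def test_unanimous_location_gets_all_votes(self, small_genome, small_index):
        text = small_genome[0].bases
        k = 2
        read = text[900:930]
        sel = gm.select_prefix_grams(read, small_index, k + 2)
        cands = gm.additional_prefix_candidates(sel, small_index, k, mode="hamming")
        at_origin = [c for c in cands if c.location == 900]
        assert at_origin and at_origin[0].votes == k + 2

    def test_merge_equals_pairwise_intersection_formula(self, small_index):
        """Two-vote merge output == union over pairs of list intersections."""
        text = small_index.sequences[0].bases
        rng = np.random.default_rng(17)
        for trial in range(40):
            k = int(rng.integers(0, 3))
            read, sel = _random_selection(rng, small_index, text, k + 2, k)
            lists = [
                set(gm.normalize_list(small_index.lookup(p.gram), p.offset))
                for p in sel.picks
            ]
            formula = set()
            for a, b in itertools.combinations(range(len(lists)), 2):
                formula |= lists[a] & lists[b]
            merged = {
                c.location
                for c in gm.additional_prefix_candidates(sel, small_index, k, mode="hamming")
            }
            assert merged == formula

    def test_two_vote_candidates_refine_the_union(self, small_index):
        """Every >=2-vote candidate lies in the union of any k+1 of the k+2 lists."""
        text = small_index.sequences[0].bases
        rng = np.random.default_rng(23)
        k = 1
        read, sel = _random_selection(rng, small_index, text, k + 2, k)
        cands = gm.additional_prefix_candidates(sel, small_index, k, mode="hamming")
        lists = [
            set(gm.normalize_list(small_index.lookup(p.gram), p.offset))
            for p in sel.picks
        ]
        for subset in itertools.combinations(range(len(lists)), k + 1):
            union = set().union(*(lists[i] for i in subset))
            for c in cands:
                assert c.location in union

    def test_hamming_survivors_of_naive_filter_survive_two_vote(
        self, small_genome, small_index
    ):
        text = small_genome[0].bases
        rng = np.random.default_rng(31)
        bases = "ACGT"
        for trial in range(10):
            k = int(rng.integers(1, 3))
            start = int(rng.integers(0, len(text) - 40))
            read = list(text[start : start + 40])
            for pos in rng.choice(40, size=k, replace=False):
                read[pos] = bases[(bases.index(read[pos]) + 1) % 4]
            read = "".join(read)
            sel = gm.select_prefix_grams(read, small_index, k + 2)
            two_vote = {
                c.location
                for c in gm.additional_prefix_candidates(sel, small_index, k, mode="hamming")
            }
            naive = {c.location for c in gm.naive_count_filter(read, small_index, k)}
            true_matches = set(brute_hamming_starts(read, text, k))
            assert (naive & true_matches) <= two_vote


@pytest.mark.parametrize("k,expected", [(1, 3), (0, 2), (5, 7)])
def test_subset_count(k, expected):
    assert gm.subset_count(k) == expected
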