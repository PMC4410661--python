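import bisect

import numpy as np
import pytest

import mosaicmatch as mm
from mosaicmatch.dictionary import lookup_batch

ORDER = mm.DEFAULT_ORDER


def word_from_ranks(ranks):
    return "".join(ORDER[r] for r in ranks)


def seq(i, label, residues):
    return mm.LabelledSequence(f"s{i}", label, residues)


class TestExtractWords:
    def test_exact_length_sequence_yields_one_word(self):
        words = list(mm.extract_words([seq(0, "F1", "ACDEFGHIKLMNPQRSTV")]))
        assert len(words) == 1
        assert words[0][1] == "F1"
        assert mm.decode_word(words[0][0]) == "ACDEFGHIKLMNPQRSTV"

    def test_short_sequence_yields_nothing(self):
        assert list(mm.extract_words([seq(0, "F1", "A" * 17)])) == []

    def test_invalid_residue_blocks_all_overlapping_windows(self):
        s = "ACDEFGHIKXLMNPQRSTV"  # length 19, X at position 10 (1-based)
        assert len(s) == 19
        assert list(mm.extract_words([seq(0, "F1", s)])) == []

    def test_lowercase_premasked_residues_are_skipped(self):
        s = "a" * 6 + "ACDEFGHIKLMNPQRSTV"
        words = list(mm.extract_words([seq(0, "F1", s)]))
        assert len(words) == 1  # only the fully-uppercase window survives


class TestEntropyMask:
    def test_homopolymer_masked_random_not(self):
        alph = mm.DEFAULT_ALPHABET
        low = alph.to_ranks("A" * 30)
        assert mm.entropy_mask(low).all()
        rng = np.random.default_rng(0)
        rand = rng.integers(0, 20, size=200).astype(np.int16)
        assert not mm.entropy_mask(rand).any()

    def test_entropy_masker_drops_low_complexity_words(self):
        s = "A" * 30 + "ACDEFGHIKLMNPQRSTVWY" * 2
        with_mask = list(
            mm.extract_words([seq(0, "F", s)], masker="entropy")
        )
        without = list(mm.extract_words([seq(0, "F", s)], masker="none"))
        assert len(with_mask) < len(without)


class TestBuildDictionary:
    def test_empty_stream(self):
        d = mm.build_dictionary([])
        assert d.n_words == 0
        assert mm.lookup(d, mm.encode_word("A" * 18)).kind == "none"

    def test_ambiguous_word_removed(self):
        w = mm.encode_word("ACDEFGHIKLMNPQRSTV")
        d = mm.build_dictionary([(w, "F1"), (w, "F2")])
        assert d.n_words == 0

    def test_duplicate_pairs_collapse(self):
        w = mm.encode_word("ACDEFGHIKLMNPQRSTV")
        d = mm.build_dictionary([(w, "F1"), (w, "F1"), (w, "F1")])
        assert d.n_words == 1

    def test_singleton_flags_hand_example(self):
        # six words already in sorted order (only the last residue varies,
        # walking up the evolutionary alphabet), labels F1,F1,F2,F1,F1,F2
        labels = ["F1", "F1", "F2", "F1", "F1", "F2"]
        stream = [
            (mm.encode_word("A" * 17 + ORDER[i]), lab)
            for i, lab in enumerate(labels)
        ]
        d = mm.build_dictionary(stream)
        assert d.n_words == 6
        assert d.singleton_mask.tolist() == [False, False, True, False, False, True]
        pruned = mm.remove_singletons(d)
        assert pruned.n_words == 4
        assert pruned.singleton_mask is None

    def test_post_pruning_neighbour_property(self):
        rng = np.random.default_rng(8)
        stream = []
        for _ in range(300):
            ranks = rng.integers(0, 20, size=18)
            stream.append((mm.encode_word(word_from_ranks(ranks)), f"F{rng.integers(4)}"))
        d = mm.remove_singletons(mm.build_dictionary(stream))
        lab = d.labels
        for i in range(d.n_words):
            neighbours = [lab[j] for j in (i - 1, i + 1) if 0 <= j < d.n_words]
            assert any(lab[i] == nl for nl in neighbours) or len(neighbours) < 2


class TestReverseDictionary:
    def test_single_word_reversed(self):
        s = "ACDEFGHIKLMNPQRSTV"
        d = mm.reverse_dictionary([seq(0, "F1", s)])
        assert d.n_words == 1
        assert d.word_string(0) == s[::-1]
        assert d.direction == "reverse"

    def test_matches_forward_pipeline_on_prereversed_sequences(self):
        rng = np.random.default_rng(4)
        seqs = [
            seq(i, f"F{i % 3}", word_from_ranks(rng.integers(0, 20, size=40)))
            for i in range(10)
        ]
        rev = mm.reverse_dictionary(seqs)
        pre = [mm.LabelledSequence(s.id, s.label, s.residues[::-1]) for s in seqs]
        fwd_of_rev, _ = mm.build_from_sequences(pre)
        assert np.array_equal(rev.suffixes, fwd_of_rev.suffixes)
        assert np.array_equal(rev.labels, fwd_of_rev.labels)
        assert np.array_equal(rev.prefix_keys, fwd_of_rev.prefix_keys)

    def test_reverse_db_of_reversed_references_equals_forward(self, tiny_families):
        # scoring symmetry at the dictionary level: the reverse dictionary of
        # the original references equals the forward dictionary of reversed ones
        members, _ = tiny_families
        some = members[:8]
        rev = mm.reverse_dictionary(some)
        fwd_flip, _ = mm.build_from_sequences(
            [mm.LabelledSequence(s.id, s.label, s.residues[::-1]) for s in some]
        )
        assert np.array_equal(rev.suffixes, fwd_flip.suffixes)
        assert np.array_equal(rev.prefix_offsets, fwd_flip.prefix_offsets)


def linear_scan_oracle(stored, query_key):
    """Insertion neighbours by sorting all words and bisecting."""
    keys = sorted(k for k, _ in stored.items())
    i = bisect.bisect_left(keys, query_key)
    if i < len(keys) and keys[i] == query_key:
        return "exact", [keys[i]]
    return "insert", [k for k in (keys[i - 1] if i else None, keys[i] if i < len(keys) else None) if k is not None]


@pytest.fixture(scope="module")
def fixture_words():
    rng = np.random.default_rng(17)
    stored = {}
    while len(stored) < 100:
        ranks = tuple(rng.integers(0, 6, size=18))  # small alphabet -> shared prefixes
        stored[ranks] = f"F{rng.integers(3)}"
    d = mm.build_dictionary(
        [(mm.encode_word(word_from_ranks(r)), lab) for r, lab in stored.items()]
    )
    return stored, d


class TestLookup:

    def test_exact_match_distance_zero(self, fixture_words):
        stored, d = fixture_words
        ranks = next(iter(sorted(stored)))
        res = mm.lookup(d, mm.encode_word(word_from_ranks(ranks)))
        assert res.kind == "exact"
        assert res.lcp_distances == (0,)
        assert res.labels == (stored[ranks],)

    def test_insert_neighbours_share_17_residues(self):
        base = [3] * 18
        lo = list(base); lo[17] = 1
        hi = list(base); hi[17] = 5
        d = mm.build_dictionary(
            [
                (mm.encode_word(word_from_ranks(lo)), "F1"),
                (mm.encode_word(word_from_ranks(hi)), "F2"),
            ]
        )
        res = mm.lookup(d, mm.encode_word(word_from_ranks(base)))
        assert res.kind == "insert"
        assert res.lcp_distances == (1, 1)

    def test_agrees_with_linear_scan_oracle(self, fixture_words):
        stored, d = fixture_words
        rng = np.random.default_rng(23)
        for _ in range(200):
            q = tuple(rng.integers(0, 6, size=18))
            kind, neighbours = linear_scan_oracle(stored, q)
            res = mm.lookup(d, mm.encode_word(word_from_ranks(q)))
            assert res.kind == kind
            got = [tuple(d.word_ranks(e)) for e in res.entries]
            assert got == neighbours
            # LCP distances against direct string comparison
            for entry_ranks, dist in zip(got, res.lcp_distances):
                lcp = 0
                for a, b in zip(q, entry_ranks):
                    if a != b:
                        break
                    lcp += 1
                assert dist == 18 - lcp

    def test_batch_lookup_matches_scalar(self, fixture_words):
        stored, d = fixture_words
        rng = np.random.default_rng(29)
        queries = [tuple(rng.integers(0, 6, size=18)) for _ in range(150)]
        enc = [mm.encode_word(word_from_ranks(q)) for q in queries]
        pref = np.array([e.prefix_code for e in enc], dtype=np.int64)
        suf = np.array([e.suffix_code for e in enc], dtype=np.int64)
        ins, exact = lookup_batch(d, pref, suf)
        for i, e in enumerate(enc):
            res = mm.lookup(d, e)
            if res.kind == "exact":
                assert exact[i]
                assert ins[i] == res.entries[0]
            else:
                assert not exact[i]
                # scalar entries are (ins-1, ins) clipped to the array range
                want = tuple(
                    e for e in (ins[i] - 1, ins[i]) if 0 <= e < d.n_words
                )
                assert want == res.entries
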