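import numpy as np
import pytest

import mosaicmatch as mm
from conftest import make_identity_db

ORDER = mm.DEFAULT_ORDER


def word_from_ranks(ranks):
    return "".join(ORDER[r] for r in ranks)


@pytest.fixture(scope="module")
def ref_db():
    rng = np.random.default_rng(12)
    seqs = [
        mm.LabelledSequence(
            f"ref{i}", f"F{i}", word_from_ranks(rng.integers(0, 20, size=60))
        )
        for i in range(3)
    ]
    return seqs, make_identity_db(seqs)


class TestClassifyWordsIdentity:
    """Hand-checkable behaviour with identity-diagonal scoring matrices."""

    def test_query_equal_to_reference_scores_12_per_window(self, ref_db):
        seqs, db = ref_db
        q = seqs[0].residues
        matches = [m for m in mm.classify_words(q, db) if m.direction == "forward"]
        exact = [m for m in matches if m.family == "F0" and m.total() == 12.0]
        assert len(exact) == len(q) - 17

    def test_full_identity_mosaic_covers_whole_sequence(self, ref_db):
        seqs, db = ref_db
        q = seqs[1].residues
        res = mm.mosaic_score(mm.classify_words(q, db), len(q))
        total, _, covered = res.per_family["F1"]
        # forward windows cover residues 6..L-1, reverse cover 0..L-7:
        # together every residue scores its diagonal value 1
        assert covered == len(q)
        assert total == pytest.approx(len(q))

    def test_short_query_yields_no_matches(self, ref_db):
        _, db = ref_db
        assert mm.classify_words("ACDEFGHIKLMNPQRST", db) == []


class TestNeighbourMaxRule:
    def test_same_family_neighbours_take_positionwise_max(self):
        base = [7] * 18
        lo = list(base); lo[6 + 3] = 6   # differs at suffix position 3, sorts lower
        hi = list(base); hi[6 + 7] = 8   # differs at suffix position 7, sorts higher
        seqs = [
            mm.LabelledSequence("a", "F1", word_from_ranks(lo)),
            mm.LabelledSequence("b", "F1", word_from_ranks(hi)),
        ]
        db = make_identity_db(seqs)
        matches = [
            m
            for m in mm.classify_words(word_from_ranks(base), db)
            if m.direction == "forward"
        ]
        # one combined match: each position takes the better neighbour score
        assert len(matches) == 1
        assert matches[0].family == "F1"
        assert np.allclose(matches[0].scores, 1.0)

    def test_different_family_neighbours_both_reported(self):
        base = [7] * 18
        lo = list(base); lo[17] = 6
        hi = list(base); hi[17] = 8
        seqs = [
            mm.LabelledSequence("a", "F1", word_from_ranks(lo)),
            mm.LabelledSequence("b", "F2", word_from_ranks(hi)),
        ]
        db = make_identity_db(seqs)
        matches = [
            m
            for m in mm.classify_words(word_from_ranks(base), db)
            if m.direction == "forward"
        ]
        assert sorted(m.family for m in matches) == ["F1", "F2"]


def brute_force_matches(query, db):
    """Independent per-window oracle: scan all stored words, apply the
    neighbour and scoring rules literally, both directions."""
    shape = db.forward.shape
    alph = db.forward.alphabet
    k, p = shape.word_length, shape.prefix_length
    out = []
    q_ranks = [alph.rank[c] for c in query]
    for dname, d, pssm in (
        ("forward", db.forward, db.pssm_forward),
        ("reverse", db.reverse, db.pssm_reverse),
    ):
        stored = sorted(
            (tuple(d.word_ranks(i)), d.family_names[int(d.labels[i])])
            for i in range(d.n_words)
        )
        keys = [w for w, _ in stored]
        for w0 in range(len(query) - k + 1):
            window = q_ranks[w0 : w0 + k]
            if dname == "reverse":
                window = window[::-1]
            window = tuple(window)
            import bisect

            i = bisect.bisect_left(keys, window)
            if i < len(keys) and keys[i] == window:
                cand = [stored[i]]
            else:
                cand = [stored[j] for j in (i - 1, i) if 0 <= j < len(stored)]
            if not cand:
                continue
            score_of = lambda ref: [
                pssm.matrices[j, window[p + j], ref[p + j]] for j in range(k - p)
            ]
            if i < len(keys) and keys[i] == window:
                emitted = [(cand[0][1], score_of(cand[0][0]))]
            elif len(cand) == 2 and cand[0][1] == cand[1][1]:
                s = np.maximum(score_of(cand[0][0]), score_of(cand[1][0]))
                emitted = [(cand[0][1], list(s))]
            else:
                emitted = [(lab, score_of(w)) for w, lab in cand]
            for fam, scores in emitted:
                out.append((dname, w0, fam, tuple(np.round(scores, 9))))
    return sorted(out)


@pytest.fixture(scope="module")
def fixture_db():
    rng = np.random.default_rng(31)
    seqs = [
        mm.LabelledSequence(
            f"r{i}", f"F{i % 3}", word_from_ranks(rng.integers(0, 5, size=40))
        )
        for i in range(6)
    ]
    fwd, _ = mm.build_from_sequences(seqs)
    rev, _ = mm.build_from_sequences(seqs, direction="reverse")
    mats = np.random.default_rng(32).normal(size=(12, 20, 20))
    from mosaicmatch.database import Database
    from mosaicmatch.pssm import PSSMSet

    return Database(
        forward=mm.remove_singletons(fwd),
        reverse=mm.remove_singletons(rev),
        pssm_forward=PSSMSet(mats, 1.0, "forward"),
        pssm_reverse=PSSMSet(mats[::-1].copy(), 1.0, "reverse"),
    )


class TestOracleEquivalence:

    def test_matches_equal_brute_force_oracle(self, fixture_db):
        rng = np.random.default_rng(33)
        for _ in range(40):
            q = word_from_ranks(rng.integers(0, 5, size=rng.integers(18, 30)))
            got = sorted(
                (
                    m.direction,
                    m.window_start,
                    m.family,
                    tuple(
                        np.round(
                            m.scores[np.argsort(m.positions)][:: (1 if m.direction == "forward" else -1)],
                            9,
                        )
                    ),
                )
                for m in mm.classify_words(q, fixture_db)
            )
            assert got == brute_force_matches(q, fixture_db)

    def test_full_path_equals_per_residue_enumeration(self, fixture_db):
        rng = np.random.default_rng(34)
        for _ in range(15):
            q = word_from_ranks(rng.integers(0, 5, size=25))
            matches = mm.classify_words(q, fixture_db)
            res = mm.mosaic_score(matches, len(q))
            # independent per-residue max-sum table
            for fam, (total, n, covered) in res.per_family.items():
                table = {}
                for m in matches:
                    if m.family != fam:
                        continue
                    for pos, s in zip(m.positions, m.scores):
                        table[pos] = max(table.get(pos, -np.inf), s)
                assert covered == len(table)
                assert total == pytest.approx(sum(table.values()), abs=1e-9)


class TestMosaicScore:
    def test_single_match_total_is_sum(self):
        match = mm.WordMatch("F1", "forward", 0, np.arange(6, 18), np.arange(12.0))
        res = mm.mosaic_score([match], 30)
        assert res.per_family["F1"][0] == pytest.approx(np.arange(12.0).sum())
        assert res.per_family["F1"][2] == 12

    def test_overlap_takes_per_residue_max(self):
        a = mm.WordMatch("F1", "forward", 0, np.arange(6, 18), np.full(12, 1.0))
        b = mm.WordMatch("F1", "forward", 6, np.arange(12, 24), np.full(12, 2.0))
        res = mm.mosaic_score([a, b], 30)
        # residues 6..11 score 1, residues 12..23 score 2
        assert res.per_family["F1"][0] == pytest.approx(6 * 1.0 + 12 * 2.0)

    def test_families_are_independent(self):
        a = mm.WordMatch("F1", "forward", 0, np.arange(6, 18), np.full(12, 1.0))
        b = mm.WordMatch("F2", "forward", 0, np.arange(6, 18), np.full(12, 3.0))
        both = mm.mosaic_score([a, b], 30)
        only_a = mm.mosaic_score([a], 30)
        assert both.per_family["F1"] == only_a.per_family["F1"]

    def test_adding_overlapping_same_family_match_never_decreases_total(self):
        # per-residue max is monotone on residues that are already covered;
        # newly covered residues may contribute negative scores, so the
        # guarantee applies to overlapping matches
        rng = np.random.default_rng(41)
        positions = np.arange(6, 18)
        matches = [mm.WordMatch("F1", "forward", 0, positions, rng.normal(size=12))]
        prev = mm.mosaic_score(matches, 40).per_family["F1"][0]
        for _ in range(5):
            matches.append(
                mm.WordMatch("F1", "forward", 0, positions, rng.normal(size=12))
            )
            total = mm.mosaic_score(matches, 40).per_family["F1"][0]
            assert total >= prev - 1e-12
            prev = total

    def test_empty_match_list(self):
        assert mm.mosaic_score([], 50).per_family == {}


class TestPredict:
    def test_thresholded_prediction(self, tiny_db, tiny_families):
        _, heldout = tiny_families
        q = heldout[0]
        hits = mm.predict(q.residues, tiny_db, tiny_db.thresholds, "default", "best")
        assert hits and hits[0][0] == q.label

    def test_all_below_threshold_is_empty(self, tiny_db):
        from mosaicmatch.calibrate import ThresholdTable

        huge = ThresholdTable(
            (32, 64, 128),
            {"default": 0.001},
            {"default": np.full(3, 1e9)},
            1000,
            0,
        )
        rng = np.random.default_rng(44)
        q = word_from_ranks(rng.integers(0, 20, size=64))
        assert mm.predict(q, tiny_db, huge, "default", "all") == []

    def test_no_threshold_reports_every_matched_family(self, tiny_db):
        rng = np.random.default_rng(45)
        q = word_from_ranks(rng.integers(0, 20, size=64))
        hits = mm.predict(q, tiny_db, None, mode="all")
        res = mm.mosaic_score(mm.classify_words(q, tiny_db), len(q))
        assert {f for f, _ in hits} == set(res.per_family)

    def test_deterministic_output(self, tiny_db, tiny_families):
        _, heldout = tiny_families
        q = heldout[3].residues
        first = mm.predict(q, tiny_db, tiny_db.thresholds, "sensitive", "all")
        second = mm.predict(q, tiny_db, tiny_db.thresholds, "sensitive", "all")
        assert first == second
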