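"""Word-level nearest-neighbour classification and the mosaic score.

Every valid 18-mer window of a query protein is looked up in the
forward dictionary and, residue-reversed, in the reverse dictionary.
An exact hit is scored against the matched word alone; otherwise the
one or two words flanking the insertion position are used: if both
flanks carry the same family label the per-position maximum of the two
substitution-score vectors gives a single match, and if the labels
differ each flank contributes its own match.  Only the 12 suffix
positions are scored; a reverse match therefore covers the *first* 12
residues of the original window (the reversed word's suffix).

The per-family mosaic score takes, at every residue covered by at
least one match of that family (either direction), the maximum
positional score, and sums those maxima over the sequence; uncovered
residues contribute zero.  Negative positional scores are kept and can
lower a family's total.  A family is reported only if it achieved at
least one word match, and a prediction additionally requires the total
to exceed a length-dependent calibrated noise threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .calibrate import ThresholdTable, threshold_for_length
from .dictionary import WordDictionary, lookup_batch

_DIR_NAMES = ("forward", "reverse")


@dataclass(frozen=True)
class WordMatch:
    """One scored word match against the database.

    ``positions`` are the 12 query-residue indices covered by the scored
    suffix positions (0-based, strictly increasing); ``scores`` is
    aligned with ``positions``.
    """

    family: str
    direction: str
    window_start: int
    positions: np.ndarray
    scores: np.ndarray

    def total(self) -> float:
        return float(self.scores.sum())


@dataclass(frozen=True)
class MosaicResult:
    """Per-family mosaic totals for one query."""

    per_family: dict  # family name -> (total_score, n_matches, covered_residues)
    query_length: int


def _pair_scores(pssm, qsr: np.ndarray, d: WordDictionary, qrows, entries) -> np.ndarray:
    """(m, l) positional scores of query rows against dictionary entries."""
    l = pssm.suffix_length
    return pssm.matrices[
        np.arange(l)[None, :], qsr[qrows].astype(np.int64), d.suffix_ranks[entries].astype(np.int64)
    ]


def _direction_matches(wd: np.ndarray, d: WordDictionary, pssm):
    """Match all query windows (rank rows ``wd``) against one dictionary.

    Returns (qrows, families, scores) where ``qrows`` indexes rows of
    ``wd`` and scores has shape (m, l) in suffix-position order.
    """
    p = d.shape.prefix_length
    pref = wd[:, :p] @ d.shape.prefix_weights
    suf = wd[:, p:] @ d.shape.suffix_weights
    qsr = wd[:, p:]
    ins, exact = lookup_batch(d, pref, suf)
    n = d.n_words
    rows_out, fam_out, sc_out = [], [], []
    if n == 0:
        return (np.empty(0, np.int64), np.empty(0, np.int64), np.empty((0, d.shape.suffix_length)))

    q_e = np.flatnonzero(exact)
    if len(q_e):
        ent = ins[q_e]
        rows_out.append(q_e)
        fam_out.append(d.labels[ent].astype(np.int64))
        sc_out.append(_pair_scores(pssm, qsr, d, q_e, ent))

    q_n = np.flatnonzero(~exact)
    if len(q_n):
        left = ins[q_n] - 1
        right = ins[q_n]
        lv = left >= 0
        rv = right < n
        lab_l = np.where(lv, d.labels[np.maximum(left, 0)], -1)
        lab_r = np.where(rv, d.labels[np.minimum(right, n - 1)], -1)
        both = lv & rv
        same = both & (lab_l == lab_r)
        if same.any():
            qq = q_n[same]
            sl = _pair_scores(pssm, qsr, d, qq, left[same])
            sr = _pair_scores(pssm, qsr, d, qq, right[same])
            rows_out.append(qq)
            fam_out.append(lab_l[same].astype(np.int64))
            sc_out.append(np.maximum(sl, sr))
        lone_l = lv & ~same  # left used on its own (labels differ or no right)
        if lone_l.any():
            qq = q_n[lone_l]
            rows_out.append(qq)
            fam_out.append(lab_l[lone_l].astype(np.int64))
            sc_out.append(_pair_scores(pssm, qsr, d, qq, left[lone_l]))
        lone_r = rv & ~same
        if lone_r.any():
            qq = q_n[lone_r]
            rows_out.append(qq)
            fam_out.append(lab_r[lone_r].astype(np.int64))
            sc_out.append(_pair_scores(pssm, qsr, d, qq, right[lone_r]))

    if not rows_out:
        return (np.empty(0, np.int64), np.empty(0, np.int64), np.empty((0, d.shape.suffix_length)))
    return (np.concatenate(rows_out), np.concatenate(fam_out), np.vstack(sc_out))


def _batch_matches(ranks2d: np.ndarray, db) -> dict:
    """Vectorised matching of a (n_seq, L) rank batch, both directions.

    Returns flat match arrays: seq, win (window start), fam, dir (0 =
    forward, 1 = reverse) and (m, l) suffix-position scores.
    """
    shape = db.forward.shape
    k = shape.word_length
    n_seq, L = ranks2d.shape
    if L < k:
        return {
            "seq": np.empty(0, np.int64), "win": np.empty(0, np.int64),
            "fam": np.empty(0, np.int64), "dir": np.empty(0, np.int8),
            "scores": np.empty((0, shape.suffix_length)),
        }
    win_view = sliding_window_view(ranks2d, k, axis=1)
    valid = (win_view >= 0).all(axis=-1)
    seq_i, win_i = np.nonzero(valid)
    w = win_view[seq_i, win_i].astype(np.int64)

    parts = {key: [] for key in ("seq", "win", "fam", "dir", "scores")}
    for dcode, (d, pssm) in enumerate(
        ((db.forward, db.pssm_forward), (db.reverse, db.pssm_reverse))
    ):
        wd = w[:, ::-1] if dcode == 1 else w
        rows, fam, sc = _direction_matches(wd, d, pssm)
        parts["seq"].append(seq_i[rows])
        parts["win"].append(win_i[rows])
        parts["fam"].append(fam)
        parts["dir"].append(np.full(len(rows), dcode, dtype=np.int8))
        parts["scores"].append(sc)
    return {
        "seq": np.concatenate(parts["seq"]),
        "win": np.concatenate(parts["win"]),
        "fam": np.concatenate(parts["fam"]),
        "dir": np.concatenate(parts["dir"]),
        "scores": np.vstack(parts["scores"]),
    }


def _match_positions(match: dict, shape) -> np.ndarray:
    """Query-residue index of every (match, suffix-position) score.

    Forward: suffix position j sits at window_start + prefix + j.
    Reverse: the reversed word's suffix position j maps back to
    window_start + (k - 1 - prefix) - j, i.e. the first 12 residues of
    the window in reverse order.
    """
    j = np.arange(shape.suffix_length)
    win = match["win"][:, None]
    fwd_pos = win + shape.prefix_length + j
    rev_pos = win + (shape.word_length - 1 - shape.prefix_length) - j
    return np.where(match["dir"][:, None] == 0, fwd_pos, rev_pos)


def _mosaic_totals(match: dict, n_seq: int, L: int, n_fam: int, shape):
    """Dense per-(sequence, family) totals from flat match arrays.

    Returns (totals, present, covered, n_matches); totals are 0 for
    absent families and may be negative for present ones.
    """
    pos = _match_positions(match, shape)
    flat = ((match["seq"][:, None] * n_fam + match["fam"][:, None]) * L + pos).ravel()
    dense = np.full(n_seq * n_fam * L, -np.inf)
    np.maximum.at(dense, flat, match["scores"].ravel())
    dense = dense.reshape(n_seq, n_fam, L)
    covered_mask = dense > -np.inf
    totals = np.where(covered_mask, dense, 0.0).sum(axis=-1)
    present = np.zeros((n_seq, n_fam), dtype=bool)
    present[match["seq"], match["fam"]] = True
    n_matches = np.zeros((n_seq, n_fam), dtype=np.int64)
    np.add.at(n_matches, (match["seq"], match["fam"]), 1)
    return totals, present, covered_mask.sum(axis=-1), n_matches


def batch_max_scores(ranks2d: np.ndarray, db, chunk: int | None = None) -> np.ndarray:
    """Per-sequence maximum per-family mosaic score for a uniform batch.

    Sequences with no word match at all score 0; sequences whose only
    matched families have negative totals keep the (negative) maximum.
    The workhorse of threshold calibration.
    """
    n_seq, L = ranks2d.shape
    n_fam = len(db.forward.family_names)
    shape = db.forward.shape
    if chunk is None:
        chunk = max(1, int(4e6 // max(n_fam * L, 1)))
    out = np.empty(n_seq)
    for s in range(0, n_seq, chunk):
        part = ranks2d[s : s + chunk]
        match = _batch_matches(part, db)
        totals, present, _, _ = _mosaic_totals(match, len(part), L, n_fam, shape)
        masked = np.where(present, totals, -np.inf)
        mx = masked.max(axis=1)
        mx[~present.any(axis=1)] = 0.0
        out[s : s + chunk] = mx
    return out


# ---------------------------------------------------------------------------
# Scalar (per-query) API
# ---------------------------------------------------------------------------

def classify_words(query: str, db) -> list[WordMatch]:
    """All scored word matches of one protein query (both directions).

    Windows containing invalid residues are skipped.  Matches are
    returned in deterministic order: direction, then window start, then
    family index.
    """
    shape = db.forward.shape
    ranks = db.forward.alphabet.to_ranks(query.upper())
    if len(ranks) < shape.word_length:
        return []
    match = _batch_matches(ranks[None, :], db)
    pos = _match_positions(match, shape)
    order = np.lexsort((match["fam"], match["win"], match["dir"]))
    out = []
    for i in order:
        p = pos[i]
        sc = match["scores"][i]
        srt = np.argsort(p)  # present positions increasing
        out.append(
            WordMatch(
                family=db.forward.family_names[int(match["fam"][i])],
                direction=_DIR_NAMES[int(match["dir"][i])],
                window_start=int(match["win"][i]),
                positions=p[srt],
                scores=sc[srt],
            )
        )
    return out


def mosaic_score(matches: list[WordMatch], query_length: int) -> MosaicResult:
    """Combine word matches into per-family totals (per-residue max, summed)."""
    fams = sorted({m.family for m in matches})
    per_family = {}
    for fam in fams:
        best = np.full(query_length, -np.inf)
        n = 0
        for m in matches:
            if m.family != fam:
                continue
            if np.any(m.positions >= query_length) or np.any(m.positions < 0):
                raise ValueError("match positions outside the query sequence")
            np.maximum.at(best, m.positions.astype(np.intp), m.scores)
            n += 1
        covered = best > -np.inf
        total = float(np.where(covered, best, 0.0).sum())
        per_family[fam] = (total, n, int(covered.sum()))
    return MosaicResult(per_family, query_length)


def predict(
    query: str,
    db,
    thresholds: ThresholdTable | None = None,
    level: str = "default",
    mode: str = "all",
) -> list[tuple[str, float]]:
    """Families whose mosaic total exceeds the calibrated noise threshold.

    ``mode='best'`` reports at most the single top-scoring family; ties
    are broken by the smaller family index.  Without a threshold table
    every matched family is reported.
    """
    if mode not in ("all", "best"):
        raise ValueError(f"unknown mode {mode!r}")
    res = mosaic_score(classify_words(query, db), len(query))
    thr = (
        threshold_for_length(thresholds, len(query), level)
        if thresholds is not None
        else -np.inf
    )
    fam_index = {name: i for i, name in enumerate(db.forward.family_names)}
    hits = [
        (fam, total)
        for fam, (total, _, _) in res.per_family.items()
        if total > thr
    ]
    hits.sort(key=lambda ft: (-ft[1], fam_index[ft[0]]))
    if mode == "best":
        hits = hits[:1]
    return hits


def format_detailed(query_id: str, matches: list[WordMatch]) -> list[str]:
    """Tab-separated diagnostic lines: one per word match."""
    lines = []
    for m in matches:
        scores = "\t".join(f"{s:.4f}" for s in m.scores)
        lines.append(
            f"{query_id}\t{m.family}\t{m.direction}\t{m.window_start}\t{scores}"
        )
    return lines
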