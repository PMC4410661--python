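"""Sorted oligopeptide dictionary: build, prune, search.

Every 18-residue window of every (unmasked) reference sequence becomes a
candidate dictionary word carrying its family label.  Words are stored
once, sorted under the evolutionary alphabet; ambiguous words (seen in
more than one family) are removed outright, and singleton words (label
differing from both sorted neighbours) are flagged for removal *after*
the scoring matrices have been trained, because they contribute
valuable negative training examples.

Only the 12-mer suffix codes are stored explicitly (64-bit integers);
a prefix table maps each occupied hexamer prefix to the contiguous
block of entries sharing it, so that a query word is located by a
binary search within its prefix block.  A second dictionary built from
residue-reversed words supports reverse matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .alphabet import (
    DEFAULT_ALPHABET,
    DEFAULT_SHAPE,
    AlphabetOrdering,
    EncodedWord,
    WordShape,
    decode_prefix_ranks,
    decode_suffix_ranks,
)

# Entropy-masker defaults: Shannon entropy of the residue composition in a
# sliding 12-residue window; windows below 2.2 bits are masked.  This is a
# deliberately simple low-complexity filter; pre-masked input (lowercase =
# masked) is honoured regardless of the masker setting.
MASK_WINDOW = 12
MASK_ENTROPY_BITS = 2.2


@dataclass(frozen=True)
class LabelledSequence:
    """A reference protein with its family label."""

    id: str
    label: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.label:
            raise ValueError(f"sequence {self.id!r}: family label must be non-empty")


def entropy_mask(
    ranks: np.ndarray,
    window: int = MASK_WINDOW,
    threshold: float = MASK_ENTROPY_BITS,
) -> np.ndarray:
    """Boolean mask of residues inside any low-entropy window.

    Entropy is computed over the composition of valid residues in each
    length-``window`` window; a window whose entropy falls below
    ``threshold`` bits masks all of its residues.
    """
    L = len(ranks)
    mask = np.zeros(L, dtype=bool)
    if L < window:
        return mask
    onehot = np.zeros((L + 1, 20), dtype=np.int32)
    valid = ranks >= 0
    onehot[1:][valid, ranks[valid].astype(np.intp)] = 1
    cs = np.cumsum(onehot, axis=0)
    counts = cs[window:] - cs[:-window]  # (L-window+1, 20)
    totals = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / np.maximum(totals, 1)[:, None]
        ent = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
    low = (ent < threshold) & (totals > 0)
    if low.any():
        # mark every residue covered by a low-entropy window
        delta = np.zeros(L + 1, dtype=np.int32)
        starts = np.flatnonzero(low)
        np.add.at(delta, starts, 1)
        np.add.at(delta, starts + window, -1)
        mask = np.cumsum(delta[:-1]) > 0
    return mask


def _sequence_ranks(
    seq: LabelledSequence, alph: AlphabetOrdering, masker: str
) -> np.ndarray:
    """Rank-encode a reference sequence; -1 marks invalid/masked residues."""
    ranks = alph.to_ranks(seq.residues).copy()
    if masker == "entropy":
        ranks[entropy_mask(ranks)] = -1
    elif masker != "none":
        raise ValueError(f"unknown masker {masker!r}")
    return ranks


def _window_codes(
    ranks: np.ndarray, shape: WordShape
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All valid word windows of a rank array -> (starts, prefix, suffix)."""
    k = shape.word_length
    if len(ranks) < k:
        return (np.empty(0, np.int64),) * 3
    win = sliding_window_view(ranks, k)
    valid = (win >= 0).all(axis=1)
    starts = np.flatnonzero(valid)
    w = win[starts].astype(np.int64)
    p = shape.prefix_length
    pref = w[:, :p] @ shape.prefix_weights
    suf = w[:, p:] @ shape.suffix_weights
    return starts, pref, suf


def extract_words(
    seqs: Iterable[LabelledSequence],
    shape: WordShape = DEFAULT_SHAPE,
    alph: AlphabetOrdering = DEFAULT_ALPHABET,
    masker: str = "none",
    reverse: bool = False,
) -> Iterator[tuple[EncodedWord, str]]:
    """Stream every valid word window (stride 1) with its family label.

    Windows overlapping masked or invalid residues are skipped; sequences
    shorter than the word length emit nothing.  With ``reverse=True``
    each window is residue-reversed before encoding.
    """
    for seq in seqs:
        ranks = _sequence_ranks(seq, alph, masker)
        if reverse:
            ranks = ranks[::-1]
        _, pref, suf = _window_codes(ranks, shape)
        for p, s in zip(pref, suf):
            yield EncodedWord(int(p), int(s)), seq.label


@dataclass
class WordDictionary:
    """Sorted, deduplicated word dictionary with a hexamer prefix table.

    ``suffixes``/``labels`` are parallel arrays sorted by
    (prefix, suffix); ``prefix_keys``/``prefix_offsets`` delimit the
    contiguous block of each occupied prefix (half-open, ``offsets`` has
    one more entry than ``keys``).  ``singleton_mask`` is present until
    :func:`remove_singletons` is applied.
    """

    shape: WordShape
    alphabet: AlphabetOrdering
    suffixes: np.ndarray  # uint64 (n,)
    labels: np.ndarray  # uint32 (n,) indices into family_names
    prefixes: np.ndarray  # uint32 (n,) prefix code per entry
    prefix_keys: np.ndarray  # uint32 (K,) sorted occupied prefixes
    prefix_offsets: np.ndarray  # int64 (K+1,)
    family_names: list[str]
    direction: str = "forward"
    singleton_mask: np.ndarray | None = None
    _suffix_ranks: np.ndarray | None = field(default=None, repr=False)
    _prefix_ranks: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_words(self) -> int:
        return len(self.suffixes)

    def prefix_block(self, prefix_code: int) -> tuple[int, int]:
        """Half-open entry range of the words sharing ``prefix_code``."""
        i = int(np.searchsorted(self.prefix_keys, prefix_code))
        if i < len(self.prefix_keys) and int(self.prefix_keys[i]) == prefix_code:
            return int(self.prefix_offsets[i]), int(self.prefix_offsets[i + 1])
        start = int(self.prefix_offsets[i])
        return start, start

    @property
    def suffix_ranks(self) -> np.ndarray:
        """(n, suffix_length) int8 rank matrix of all stored suffixes."""
        if self._suffix_ranks is None or len(self._suffix_ranks) != self.n_words:
            self._suffix_ranks = decode_suffix_ranks(
                self.suffixes.astype(np.int64), self.shape
            )
        return self._suffix_ranks

    @property
    def prefix_ranks(self) -> np.ndarray:
        if self._prefix_ranks is None or len(self._prefix_ranks) != self.n_words:
            self._prefix_ranks = decode_prefix_ranks(
                self.prefixes.astype(np.int64), self.shape
            )
        return self._prefix_ranks

    def word_ranks(self, i: int) -> np.ndarray:
        """Full 18-position rank vector of entry ``i``."""
        return np.concatenate([self.prefix_ranks[i], self.suffix_ranks[i]])

    def word(self, i: int) -> EncodedWord:
        return EncodedWord(int(self.prefixes[i]), int(self.suffixes[i]))

    def word_string(self, i: int) -> str:
        return self.alphabet.from_ranks(self.word_ranks(i))


def _build_from_arrays(
    pref: np.ndarray,
    suf: np.ndarray,
    lab: np.ndarray,
    family_names: list[str],
    shape: WordShape,
    alph: AlphabetOrdering,
    direction: str,
) -> tuple[WordDictionary, dict]:
    """Dedup, ambiguity-prune, sort, singleton-flag, index.  Returns stats."""
    stats = {"submitted": int(len(pref))}
    if len(pref) == 0:
        empty = WordDictionary(
            shape, alph,
            np.empty(0, np.uint64), np.empty(0, np.uint32), np.empty(0, np.uint32),
            np.empty(0, np.uint32), np.zeros(1, np.int64),
            family_names, direction, np.empty(0, bool),
        )
        stats.update(unique=0, ambiguous_removed=0, kept=0, singletons_flagged=0)
        return empty, stats

    order = np.lexsort((lab, suf, pref))
    pref, suf, lab = pref[order], suf[order], lab[order]
    # collapse identical (word, label) triples
    new = np.r_[True, (pref[1:] != pref[:-1]) | (suf[1:] != suf[:-1]) | (lab[1:] != lab[:-1])]
    pref, suf, lab = pref[new], suf[new], lab[new]
    # a word now repeats iff it carries >= 2 distinct labels -> remove it
    word_new = np.r_[True, (pref[1:] != pref[:-1]) | (suf[1:] != suf[:-1])]
    group_id = np.cumsum(word_new) - 1
    group_sizes = np.bincount(group_id)
    keep = group_sizes[group_id] == 1
    stats["unique"] = int(group_sizes.size)
    stats["ambiguous_removed"] = int((group_sizes > 1).sum())
    pref, suf, lab = pref[keep], suf[keep], lab[keep]
    n = len(pref)
    stats["kept"] = int(n)

    # singleton flags on the final sorted order (single pass, no cascade)
    sing = np.zeros(n, dtype=bool)
    if n >= 2:
        diff_prev = np.r_[True, lab[1:] != lab[:-1]]
        diff_next = np.r_[lab[:-1] != lab[1:], True]
        sing = diff_prev & diff_next
    stats["singletons_flagged"] = int(sing.sum())

    keys, starts = np.unique(pref, return_index=True)
    offsets = np.append(starts, n).astype(np.int64)
    d = WordDictionary(
        shape, alph,
        suf.astype(np.uint64), lab.astype(np.uint32), pref.astype(np.uint32),
        keys.astype(np.uint32), offsets,
        family_names, direction, sing,
    )
    return d, stats


def build_dictionary(
    words: Iterable[tuple[EncodedWord, str]],
    shape: WordShape = DEFAULT_SHAPE,
    alph: AlphabetOrdering = DEFAULT_ALPHABET,
    direction: str = "forward",
    family_names: list[str] | None = None,
) -> WordDictionary:
    """Build a dictionary from a (word, label) stream.

    Duplicate (word, label) pairs collapse silently; words seen under
    two or more distinct labels are removed unconditionally; singleton
    words are flagged (not yet removed).  An empty stream yields a valid
    empty dictionary.
    """
    pairs = list(words)
    labels_seen = sorted({lab for _, lab in pairs})
    if family_names is None:
        family_names = labels_seen
    else:
        missing = set(labels_seen) - set(family_names)
        if missing:
            raise ValueError(f"labels not in family_names: {sorted(missing)}")
    fam_idx = {name: i for i, name in enumerate(family_names)}
    pref = np.array([w.prefix_code for w, _ in pairs], dtype=np.int64)
    suf = np.array([w.suffix_code for w, _ in pairs], dtype=np.int64)
    lab = np.array([fam_idx[l] for _, l in pairs], dtype=np.int64)
    d, _ = _build_from_arrays(pref, suf, lab, family_names, shape, alph, direction)
    return d


def build_from_sequences(
    seqs: list[LabelledSequence],
    shape: WordShape = DEFAULT_SHAPE,
    alph: AlphabetOrdering = DEFAULT_ALPHABET,
    masker: str = "none",
    direction: str = "forward",
    family_names: list[str] | None = None,
) -> tuple[WordDictionary, dict]:
    """Vectorised extract + build for a sequence collection (with stats)."""
    if family_names is None:
        family_names = sorted({s.label for s in seqs})
    fam_idx = {name: i for i, name in enumerate(family_names)}
    prefs, sufs, labs = [], [], []
    n_windows = 0
    for seq in seqs:
        ranks = _sequence_ranks(seq, alph, masker)
        if direction == "reverse":
            ranks = ranks[::-1]
        n_windows += max(len(ranks) - shape.word_length + 1, 0)
        _, p, s = _window_codes(ranks, shape)
        prefs.append(p)
        sufs.append(s)
        labs.append(np.full(len(p), fam_idx[seq.label], dtype=np.int64))
    pref = np.concatenate(prefs) if prefs else np.empty(0, np.int64)
    suf = np.concatenate(sufs) if sufs else np.empty(0, np.int64)
    lab = np.concatenate(labs) if labs else np.empty(0, np.int64)
    d, stats = _build_from_arrays(pref, suf, lab, family_names, shape, alph, direction)
    stats["windows_total"] = int(n_windows)
    stats["windows_skipped"] = int(n_windows - len(pref))
    return d, stats


def reverse_dictionary(
    seqs: list[LabelledSequence],
    shape: WordShape = DEFAULT_SHAPE,
    alph: AlphabetOrdering = DEFAULT_ALPHABET,
    masker: str = "none",
    family_names: list[str] | None = None,
) -> WordDictionary:
    """Dictionary of residue-reversed words (for reverse matching)."""
    d, _ = build_from_sequences(
        seqs, shape, alph, masker, direction="reverse", family_names=family_names
    )
    return d


def remove_singletons(d: WordDictionary) -> WordDictionary:
    """Drop flagged singleton words and rebuild the prefix table.

    Flags come from the original sorted neighbourhood (single pass); the
    removal is deferred until after PSSM training, which consumes the
    singletons as negative examples.
    """
    if d.singleton_mask is None:
        return d
    keep = ~d.singleton_mask
    pref = d.prefixes[keep]
    suf = d.suffixes[keep]
    lab = d.labels[keep]
    keys, starts = np.unique(pref, return_index=True)
    offsets = np.append(starts, len(pref)).astype(np.int64)
    return WordDictionary(
        d.shape, d.alphabet, suf, lab, pref,
        keys.astype(np.uint32), offsets,
        d.family_names, d.direction, None,
    )


# ---------------------------------------------------------------------------
# Lookup
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchNeighbours:
    """Result of a dictionary lookup.

    ``kind`` is ``exact`` (one matching entry), ``insert`` (one or two
    flanking entries around the insertion position) or ``none`` (empty
    dictionary).  ``lcp_distances`` are word length minus the longest
    common prefix over all 18 positions.
    """

    kind: str
    entries: tuple[int, ...]
    labels: tuple[str, ...]
    lcp_distances: tuple[int, ...]


def _lcp_distance(d: WordDictionary, q_ranks: np.ndarray, entry: int) -> int:
    ref = d.word_ranks(entry)
    neq = np.flatnonzero(q_ranks != ref)
    lcp = int(neq[0]) if len(neq) else d.shape.word_length
    return d.shape.word_length - lcp


def lookup(d: WordDictionary, q: EncodedWord) -> MatchNeighbours:
    """Locate a query word: exact entry or its sorted-order neighbours.

    A query whose hexamer prefix block is empty is placed at its
    insertion position in the *global* sorted array, so the flanking
    words of the adjacent blocks are returned.
    """
    if d.n_words == 0:
        return MatchNeighbours("none", (), (), ())
    lo, hi = d.prefix_block(q.prefix_code)
    ins = lo + int(np.searchsorted(d.suffixes[lo:hi], np.uint64(q.suffix_code)))
    if ins < hi and int(d.suffixes[ins]) == q.suffix_code:
        entries = (ins,)
        kind = "exact"
    else:
        kind = "insert"
        entries = tuple(
            e for e in (ins - 1, ins) if 0 <= e < d.n_words
        )
    q_ranks = np.concatenate(
        [
            decode_prefix_ranks(np.array([q.prefix_code]), d.shape)[0],
            decode_suffix_ranks(np.array([q.suffix_code]), d.shape)[0],
        ]
    )
    return MatchNeighbours(
        kind,
        entries,
        tuple(d.family_names[int(d.labels[e])] for e in entries),
        tuple(_lcp_distance(d, q_ranks, e) for e in entries),
    )


def lookup_batch(
    d: WordDictionary, pref: np.ndarray, suf: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised lookup: global insertion index and exact-match flag.

    The insertion index ``ins`` satisfies: all entries < ins sort before
    the query, all entries >= ins sort after-or-equal.  ``exact[i]``
    marks queries equal to entry ``ins[i]``.
    """
    n = d.n_words
    m = len(pref)
    if n == 0:
        return np.zeros(m, np.int64), np.zeros(m, bool)
    K = len(d.prefix_keys)
    bi = np.searchsorted(d.prefix_keys, pref.astype(np.uint32))
    occ = np.zeros(m, bool)
    inb = bi < K
    occ[inb] = d.prefix_keys[bi[inb]] == pref.astype(np.uint32)[inb]
    ins = d.prefix_offsets[bi].astype(np.int64)  # block start of next >= prefix
    exact = np.zeros(m, bool)
    idx = np.flatnonzero(occ)
    if len(idx):
        lo = d.prefix_offsets[bi[idx]].astype(np.int64)
        hi0 = d.prefix_offsets[bi[idx] + 1].astype(np.int64)
        hi = hi0.copy()
        s = suf[idx].astype(np.uint64)
        sa = d.suffixes
        while True:
            active = lo < hi
            if not active.any():
                break
            mid = (lo + hi) >> 1
            less = np.zeros(len(lo), bool)
            am = mid[active]
            less[active] = sa[am] < s[active]
            lo = np.where(active & less, mid + 1, lo)
            hi = np.where(active & ~less, mid, hi)
        ins[idx] = lo
        hit = lo < hi0
        sub = np.flatnonzero(hit)
        if len(sub):
            hit[sub] = sa[lo[sub]] == s[sub]
        exact[idx] = hit
    return ins, exact
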