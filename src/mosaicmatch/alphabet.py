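"""Amino-acid alphabet handling for the oligopeptide dictionary.

The word dictionary sorts 18-mer oligopeptides under a permuted,
"evolutionary" amino-acid alphabet chosen so that lexicographically
adjacent words tend to belong to the same protein family.  The
permutation is derived from a 20x20 amino-acid scoring matrix ``S``:
letters ``i`` and ``j`` are compared through the cosine dissimilarity of
the corresponding matrix columns,

    d_ij = 1 - s_i . s_j / (||s_i|| ||s_j||),

and the alphabet order is the shortest cyclic path through all 20
letters under that distance.  The default ordering shipped with the
package is the constant ``ATSPGNDEQKRHYWFMLIVC``; :func:`alphabet_distance`
and :func:`shortest_cyclic_order` let users recompute an ordering from
their own scoring matrix, but the shipped constant is never recomputed
at database-build time so that databases are bit-stable.

Words are stored as order-preserving integer codes: the first residue is
the most significant digit, so numeric comparison of
``(prefix_code, suffix_code)`` pairs equals lexicographic comparison of
the underlying words under the evolutionary ranks.  The 12-residue
suffix code fits a 64-bit unsigned integer (12 * log2(20) < 64).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 20 standard amino acids in conventional alphabetical order.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default evolutionary ordering used by all downstream modules.
DEFAULT_ORDER = "ATSPGNDEQKRHYWFMLIVC"


class InvalidWordError(ValueError):
    """Raised when a word contains a residue outside the 20-letter alphabet.

    Callers building a dictionary catch this and skip the offending
    window: substituting a wrong residue would poison the word's
    position in the sorted dictionary.
    """


@dataclass(frozen=True)
class AlphabetOrdering:
    """A permutation of the 20 standard amino acids with rank maps."""

    order: str = DEFAULT_ORDER
    rank: dict[str, int] = field(init=False, repr=False)
    inverse: dict[int, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if sorted(self.order) != sorted(STANDARD_AMINO_ACIDS):
            raise ValueError(
                "order must be a permutation of the 20 standard amino acids, "
                f"got {self.order!r}"
            )
        object.__setattr__(self, "rank", {c: i for i, c in enumerate(self.order)})
        object.__setattr__(self, "inverse", {i: c for i, c in enumerate(self.order)})
        # ascii -> rank lookup table (-1 = not a standard residue)
        table = np.full(256, -1, dtype=np.int16)
        for i, c in enumerate(self.order):
            table[ord(c)] = i
        object.__setattr__(self, "_table", table)

    def to_ranks(self, seq: str) -> np.ndarray:
        """Encode a residue string as an int16 rank array (-1 = invalid).

        Lowercase letters (the pre-masked convention) and any character
        outside the 20-letter alphabet map to -1.
        """
        raw = np.frombuffer(seq.encode("latin-1", errors="replace"), dtype=np.uint8)
        return self._table[raw]

    def from_ranks(self, ranks) -> str:
        return "".join(self.inverse[int(r)] for r in ranks)


#: Shared default instance.
DEFAULT_ALPHABET = AlphabetOrdering(DEFAULT_ORDER)


@dataclass(frozen=True)
class WordShape:
    """Geometry of dictionary words: hexamer prefix + 12-mer suffix."""

    word_length: int = 18
    prefix_length: int = 6
    suffix_length: int = 12

    def __post_init__(self) -> None:
        if self.prefix_length + self.suffix_length != self.word_length:
            raise ValueError("prefix_length + suffix_length must equal word_length")
        if self.prefix_length < 1 or self.suffix_length < 1:
            raise ValueError("prefix and suffix lengths must be positive")
        if self.suffix_length * np.log2(20) > 64:
            raise ValueError("suffix code must fit a 64-bit unsigned integer")

    @property
    def prefix_weights(self) -> np.ndarray:
        """Base-20 digit weights for the prefix, first residue most significant."""
        return 20 ** np.arange(self.prefix_length - 1, -1, -1, dtype=np.int64)

    @property
    def suffix_weights(self) -> np.ndarray:
        return 20 ** np.arange(self.suffix_length - 1, -1, -1, dtype=np.int64)


DEFAULT_SHAPE = WordShape()


@dataclass(frozen=True, order=True)
class EncodedWord:
    """Order-preserving integer encoding of one dictionary word."""

    prefix_code: int
    suffix_code: int


# ---------------------------------------------------------------------------
# Evolutionary ordering from a scoring matrix
# ---------------------------------------------------------------------------

def read_scoring_matrix(path) -> tuple[list[str], np.ndarray]:
    """Read a whitespace-delimited 20x20 substitution-matrix text table.

    Expects one header row of amino-acid letters and one leading letter
    per data row (the common substitution-matrix dialect).  Returns the
    column letters and the matrix with rows ordered like the columns.
    """
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip() and not ln.startswith("#")]
    header = [tok.upper() for tok in lines[0]]
    if len(header) < 20:
        raise ValueError("scoring-matrix header must list at least 20 letters")
    rows: dict[str, list[float]] = {}
    for toks in lines[1:]:
        rows[toks[0].upper()] = [float(x) for x in toks[1 : len(header) + 1]]
    letters = [c for c in header if c in STANDARD_AMINO_ACIDS]
    if len(letters) != 20:
        raise ValueError("scoring matrix must cover the 20 standard amino acids")
    idx = [header.index(c) for c in letters]
    mat = np.array([[rows[r][j] for j in idx] for r in letters], dtype=float)
    return letters, mat


def alphabet_distance(S: np.ndarray, letters: str | list[str] | None = None) -> np.ndarray:
    """Pairwise cosine dissimilarity of scoring-matrix columns.

    ``d[i, j] = 1 - s_i.s_j / (||s_i|| ||s_j||)`` where ``s_i`` is column
    ``i`` of ``S``.  The result is symmetric with a zero diagonal and
    values in [0, 2].
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be a square matrix")
    norms = np.linalg.norm(S, axis=0)
    if np.any(norms == 0):
        bad = int(np.argmax(norms == 0))
        name = (letters[bad] if letters is not None else f"column {bad}")
        raise ValueError(f"zero-norm scoring-matrix column for amino acid {name}")
    cos = (S.T @ S) / np.outer(norms, norms)
    d = 1.0 - cos
    np.fill_diagonal(d, 0.0)
    # enforce exact symmetry against floating-point asymmetry
    return (d + d.T) / 2.0


def tour_length(D: np.ndarray, tour: list[int] | np.ndarray) -> float:
    """Total length of the cyclic tour visiting ``tour`` in order."""
    tour = list(tour)
    return float(sum(D[tour[i], tour[(i + 1) % len(tour)]] for i in range(len(tour))))


def _held_karp_cycle(D: np.ndarray) -> list[int]:
    """Exact shortest cyclic tour by dynamic programming (n <= 12)."""
    n = len(D)
    if n <= 2:
        return list(range(n))
    m = n - 1  # nodes 1..n-1; node 0 fixed as anchor
    full = 1 << m
    dp = np.full((full, m), np.inf)
    parent = np.full((full, m), -1, dtype=np.int32)
    for j in range(m):
        dp[1 << j, j] = D[0, j + 1]
    for mask in range(full):
        row = dp[mask]
        for j in range(m):
            cur = row[j]
            if not np.isfinite(cur) or not (mask >> j) & 1:
                continue
            for k in range(m):
                if (mask >> k) & 1:
                    continue
                nm = mask | (1 << k)
                cand = cur + D[j + 1, k + 1]
                if cand < dp[nm, k]:
                    dp[nm, k] = cand
                    parent[nm, k] = j
    closing = dp[full - 1] + D[1:, 0]
    j = int(np.argmin(closing))
    tour = [j + 1]
    mask = full - 1
    while parent[mask, j] >= 0:
        pj = int(parent[mask, j])
        mask ^= 1 << j
        j = pj
        tour.append(j + 1)
    tour.append(0)
    return tour[::-1]


def _nearest_neighbour_tour(D: np.ndarray, start: int = 0) -> list[int]:
    n = len(D)
    unvisited = set(range(n)) - {start}
    tour = [start]
    while unvisited:
        cur = tour[-1]
        nxt = min(unvisited, key=lambda j: (D[cur, j], j))
        tour.append(nxt)
        unvisited.remove(nxt)
    return tour


def _two_opt(D: np.ndarray, tour: list[int], max_sweeps: int = 200) -> list[int]:
    n = len(tour)
    tour = list(tour)
    for _ in range(max_sweeps):
        improved = False
        for i in range(n - 1):
            for j in range(i + 2, n):
                a, b = tour[i], tour[(i + 1) % n]
                c, d = tour[j], tour[(j + 1) % n]
                if a == d:
                    continue
                delta = D[a, c] + D[b, d] - D[a, b] - D[c, d]
                if delta < -1e-12:
                    tour[i + 1 : j + 1] = tour[i + 1 : j + 1][::-1]
                    improved = True
        if not improved:
            break
    return tour


def _canonical_cycle(letters: list[str]) -> str:
    """Rotate/reflect a cyclic tour to its canonical representation.

    The lexicographically smallest letter starts the ordering and the
    direction is chosen so that the second letter precedes the last one
    alphabetically, making the result unique among the 2n equivalent
    tour writings.
    """
    i = letters.index(min(letters))
    rot = letters[i:] + letters[:i]
    if len(rot) > 2 and rot[1] > rot[-1]:
        rot = [rot[0]] + rot[:0:-1]
    return "".join(rot)


def shortest_cyclic_order(
    D: np.ndarray,
    letters: str | list[str] | None = None,
    method: str = "heuristic",
) -> "AlphabetOrdering | str":
    """Order letters along the shortest cyclic path under distance ``D``.

    ``method='exact'`` (Held-Karp, alphabet size <= 12, intended for
    testing) returns a global optimum; ``method='heuristic'`` runs a
    nearest-neighbour construction refined by 2-opt with a fixed sweep
    budget and is guaranteed not to be worse than the identity ordering.
    Returns an :class:`AlphabetOrdering` when called on all 20 amino
    acids, else the canonical ordered letter string.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T):
        raise ValueError("D must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("D must have a zero diagonal")
    n = len(D)
    if letters is None:
        if n != 20:
            raise ValueError("letters must be given for non-20-letter alphabets")
        letters = STANDARD_AMINO_ACIDS
    letters = list(letters)

    if method == "exact":
        if n > 12:
            raise ValueError("exact method is limited to alphabets of size <= 12")
        tour = _held_karp_cycle(D)
    elif method == "heuristic":
        tour = _two_opt(D, _nearest_neighbour_tour(D))
        if tour_length(D, tour) > tour_length(D, list(range(n))):
            tour = list(range(n))
    else:
        raise ValueError(f"unknown method {method!r}")

    ordered = _canonical_cycle([letters[i] for i in tour])
    if n == 20:
        return AlphabetOrdering(ordered)
    return ordered


# ---------------------------------------------------------------------------
# Word encoding
# ---------------------------------------------------------------------------

def encode_word(
    word: str,
    shape: WordShape = DEFAULT_SHAPE,
    alph: AlphabetOrdering = DEFAULT_ALPHABET,
) -> EncodedWord:
    """Encode an 18-mer as an order-preserving (prefix, suffix) code pair.

    Raises :class:`InvalidWordError` on any residue outside the 20-letter
    alphabet (X, B, Z, U, ``*``, gaps, lowercase-masked residues).
    """
    if len(word) != shape.word_length:
        raise InvalidWordError(
            f"word length {len(word)} != {shape.word_length}: {word!r}"
        )
    ranks = alph.to_ranks(word)
    if np.any(ranks < 0):
        bad = word[int(np.argmax(ranks < 0))]
        raise InvalidWordError(f"unrepresentable residue {bad!r} in word {word!r}")
    p = shape.prefix_length
    prefix_code = int(ranks[:p].astype(np.int64) @ shape.prefix_weights)
    suffix_code = int(ranks[p:].astype(np.int64) @ shape.suffix_weights)
    return EncodedWord(prefix_code, suffix_code)


def decode_word(
    ew: EncodedWord,
    shape: WordShape = DEFAULT_SHAPE,
    alph: AlphabetOrdering = DEFAULT_ALPHABET,
) -> str:
    """Inverse of :func:`encode_word`."""
    out = []
    code = ew.prefix_code
    for w in shape.prefix_weights:
        d, code = divmod(code, int(w))
        out.append(alph.inverse[int(d)])
    code = ew.suffix_code
    for w in shape.suffix_weights:
        d, code = divmod(code, int(w))
        out.append(alph.inverse[int(d)])
    return "".join(out)


def decode_suffix_ranks(suffix_codes: np.ndarray, shape: WordShape) -> np.ndarray:
    """Vectorised decode of suffix codes to per-position ranks (n, l)."""
    codes = np.asarray(suffix_codes, dtype=np.int64)
    out = np.empty((len(codes), shape.suffix_length), dtype=np.int8)
    for j, w in enumerate(shape.suffix_weights):
        out[:, j] = codes // int(w) % 20
    return out


def decode_prefix_ranks(prefix_codes: np.ndarray, shape: WordShape) -> np.ndarray:
    """Vectorised decode of prefix codes to per-position ranks (n, p)."""
    codes = np.asarray(prefix_codes, dtype=np.int64)
    out = np.empty((len(codes), shape.prefix_length), dtype=np.int8)
    for j, w in enumerate(shape.prefix_weights):
        out[:, j] = codes // int(w) % 20
    return out
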