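"""Position-specific scoring matrices learned from adjacent-word pairs.

Each pair of adjacent dictionary words (i, i+1) is a training example:
the target is +1 when the two words carry the same family label (a
correct nearest-neighbour match) and -1 otherwise.  The features are
the per-position substitutions between the two words, restricted to the
12 suffix positions -- one-hot indicators over 20x20 residue pairs per
position, 12*400 = 4800 features in total, with no intercept.  A ridge
(regularised least-squares) fit of these targets yields one 20x20
scoring matrix W_j per suffix position; the prediction for a pair is
sum_j W_j[a_j, b_j], where a_j/b_j are the residues of the earlier/later
word.  At classification time the query takes the earlier-word (row)
role; matrices are not symmetrised.

The regularisation strength lambda is selected on held-out pairs: the
training set consists of all pairs with at least one "mixed" endpoint
(a dictionary location whose two incident pairs have opposite signs);
all remaining pairs validate lambda by sign-agreement accuracy.
Training happens before singleton removal, so singleton words supply
negative examples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse

from .alphabet import EncodedWord, decode_suffix_ranks
from .dictionary import WordDictionary

#: Default lambda grid: 10 points log-spaced over the shrinkage regimes.
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-2, 4, 10))

#: Above this training-set size the solver switches from the dense
#: eigendecomposition of the Gram matrix to conjugate gradients.
_CG_PAIR_THRESHOLD = 10**6
_CG_TOL = 1e-8


@dataclass(frozen=True)
class TrainingPair:
    """One adjacent-word example (scalar view, used by tests/diagnostics)."""

    i: int
    word_i: EncodedWord
    word_next: EncodedWord
    y: int


@dataclass
class TrainingSplit:
    """Adjacent-pair indices split into training and validation sets.

    ``train_idx``/``val_idx`` hold pair start locations ``i`` (the pair
    is (i, i+1)); they are disjoint and their union covers all n-1
    adjacent pairs.  ``suffix_ranks`` and ``y`` are carried along so the
    fit does not need the dictionary again.
    """

    train_idx: np.ndarray
    val_idx: np.ndarray
    suffix_ranks: np.ndarray  # (n_words, l) int8
    y: np.ndarray  # (n_words - 1,) float, +/-1

    @property
    def n_pairs(self) -> int:
        return len(self.y)

    def pairs(self, which: str = "train") -> list[TrainingPair]:
        idx = self.train_idx if which == "train" else self.val_idx
        return [TrainingPair(int(i), None, None, int(self.y[i])) for i in idx]


@dataclass
class PSSMSet:
    """l position-specific 20x20 scoring matrices plus fit metadata."""

    matrices: np.ndarray  # (l, 20, 20) float64, [j, query_rank, reference_rank]
    lam: float
    direction: str = "forward"
    orientation: str = "query_rows"

    def __post_init__(self) -> None:
        if self.matrices.ndim != 3 or self.matrices.shape[1:] != (20, 20):
            raise ValueError("matrices must have shape (l, 20, 20)")
        if not np.all(np.isfinite(self.matrices)):
            raise ValueError("PSSM entries must be finite")

    @property
    def suffix_length(self) -> int:
        return self.matrices.shape[0]


def make_training_split(d: WordDictionary) -> TrainingSplit:
    """Partition adjacent pairs of a (pre-singleton-removal) dictionary.

    A location is *mixed* when its two incident adjacent pairs have
    opposite signs; a pair trains iff either endpoint is mixed.
    Boundary locations (single incident pair) are never mixed.
    Dictionaries with fewer than two words yield an empty split.
    """
    n = d.n_words
    sr = d.suffix_ranks
    if n < 2:
        empty = np.empty(0, np.int64)
        return TrainingSplit(empty, empty, sr, np.empty(0, float))
    lab = d.labels
    y = np.where(lab[:-1] == lab[1:], 1.0, -1.0)
    mixed = np.zeros(n, dtype=bool)
    if n >= 3:
        mixed[1:-1] = y[:-1] != y[1:]
    train_mask = mixed[:-1] | mixed[1:]
    train_idx = np.flatnonzero(train_mask).astype(np.int64)
    val_idx = np.flatnonzero(~train_mask).astype(np.int64)
    return TrainingSplit(train_idx, val_idx, sr, y)


def _feature_matrix(split: TrainingSplit, idx: np.ndarray) -> scipy.sparse.csr_matrix:
    """Sparse one-hot substitution features for the pairs starting at idx."""
    l = split.suffix_ranks.shape[1]
    a = split.suffix_ranks[idx].astype(np.int64)  # earlier word
    b = split.suffix_ranks[idx + 1].astype(np.int64)  # later word
    cols = (np.arange(l)[None, :] * 400 + a * 20 + b).ravel()
    rows = np.repeat(np.arange(len(idx)), l)
    data = np.ones(len(cols), dtype=np.float64)
    return scipy.sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(idx), l * 400)
    )


def _solve_ridge_path(
    X: scipy.sparse.csr_matrix, y: np.ndarray, lambdas: np.ndarray
) -> np.ndarray:
    """Ridge solutions for every lambda; returns (n_lambda, n_features).

    Features never active in training have exactly zero weight under
    ridge, so the system is solved on the active columns only.  The
    Gram matrix is eigendecomposed once and shared across the grid;
    beyond ``_CG_PAIR_THRESHOLD`` pairs a conjugate-gradient solve per
    lambda is used instead.
    """
    n_feat = X.shape[1]
    active = np.flatnonzero(X.getnnz(axis=0) > 0)
    Xa = X[:, active]
    b = Xa.T @ y
    out = np.zeros((len(lambdas), n_feat))
    if X.shape[0] < _CG_PAIR_THRESHOLD:
        G = (Xa.T @ Xa).toarray()
        evals, evecs = scipy.linalg.eigh(G)
        vb = evecs.T @ b
        for li, lam in enumerate(lambdas):
            out[li, active] = evecs @ (vb / (evals + lam))
    else:  # pragma: no cover - large-database path, oracle-checked on small data
        G = Xa.T @ Xa
        ident = scipy.sparse.identity(G.shape[0], format="csr")
        for li, lam in enumerate(lambdas):
            w, info = scipy.sparse.linalg.cg(G + lam * ident, b, rtol=_CG_TOL)
            if info != 0:
                raise RuntimeError(f"conjugate gradients failed to converge (lambda={lam})")
            out[li, active] = w
    return out


def fit(
    split: TrainingSplit,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    direction: str = "forward",
    return_diagnostics: bool = False,
):
    """Fit the PSSM set over a lambda grid and select by validation accuracy.

    Prediction threshold is 0; validation ties (prediction exactly 0)
    count as negative predictions.  With an empty validation set the
    training-set accuracy is used as a fallback.  Raises ``ValueError``
    when the training targets are all one class (enlarge the synthetic
    fixture so family boundaries appear in the sorted dictionary).
    """
    lambdas = np.asarray(sorted(lambda_grid), dtype=float)
    if len(lambdas) == 0 or np.any(lambdas <= 0):
        raise ValueError("lambda_grid must contain positive values")
    if len(split.train_idx) == 0:
        raise ValueError(
            "empty training set: no mixed dictionary locations; "
            "use a larger synthetic fixture with interleaved families"
        )
    y_tr = split.y[split.train_idx]
    if np.all(y_tr > 0) or np.all(y_tr < 0):
        raise ValueError(
            "training targets are all one class; "
            "use a larger synthetic fixture with interleaved families"
        )
    l = split.suffix_ranks.shape[1]
    X_tr = _feature_matrix(split, split.train_idx)
    W_path = _solve_ridge_path(X_tr, y_tr, lambdas)

    if len(split.val_idx):
        X_ev = _feature_matrix(split, split.val_idx)
        y_ev = split.y[split.val_idx]
    else:
        X_ev, y_ev = X_tr, y_tr
    pred = X_ev @ W_path.T  # (n_val, n_lambda)
    sign = np.where(pred > 0, 1.0, -1.0)  # ties count as negative
    acc = (sign == y_ev[:, None]).mean(axis=0)
    resid = np.array(
        [np.sum((y_tr - X_tr @ W_path[i]) ** 2) for i in range(len(lambdas))]
    )
    best = int(np.argmax(acc))  # argmax takes the first (smallest lambda) on ties
    pssm = PSSMSet(
        W_path[best].reshape(l, 20, 20).copy(), float(lambdas[best]), direction
    )
    if return_diagnostics:
        diag = {
            "lambdas": lambdas,
            "validation_accuracy": acc,
            "train_residual": resid,
            "n_train": int(len(split.train_idx)),
            "n_validation": int(len(split.val_idx)),
        }
        return pssm, diag
    return pssm


def ssw_profile(pssm: PSSMSet) -> np.ndarray:
    """Per-position sum of squared weights, tr(W_j^T W_j).

    The profile measures how much each suffix position contributes to
    the discrimination between correct and false word matches.
    """
    return np.einsum("jab,jab->j", pssm.matrices, pssm.matrices)


def score_word_pair(
    pssm: PSSMSet, query_suffix_ranks: np.ndarray, ref_suffix_ranks: np.ndarray
) -> np.ndarray:
    """Positional substitution scores W_j[query_j, ref_j] over the suffix."""
    q = np.asarray(query_suffix_ranks, dtype=np.int64)
    r = np.asarray(ref_suffix_ranks, dtype=np.int64)
    l = pssm.suffix_length
    if q.shape[-1] != l or r.shape[-1] != l:
        raise ValueError(f"expected {l} suffix positions")
    return pssm.matrices[np.arange(l), q, r]


def score_encoded_pair(
    pssm: PSSMSet, query: EncodedWord, ref: EncodedWord, shape
) -> np.ndarray:
    """Convenience wrapper scoring two encoded words' suffixes."""
    q = decode_suffix_ranks(np.array([query.suffix_code]), shape)[0]
    r = decode_suffix_ranks(np.array([ref.suffix_code]), shape)[0]
    return score_word_pair(pssm, q, r)
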