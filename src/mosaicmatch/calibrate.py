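"""Noise-threshold calibration on random protein sequences.

Mosaic totals of a query grow with its length even on random input, so
prediction thresholds are calibrated per length: for each length in a
geometric spectrum (32, 64, 128, 256, 512, 1024 aa) a large sample of
i.i.d. random proteins (residues drawn from bundled background
frequencies) is classified and the threshold for a false-positive rate
``f`` is the empirical (1 - f) quantile (higher/conservative order
statistic) of the per-sequence maximum family score.  The default
prediction level targets a 0.1% FPR; the alternative "sensitive" level
targets 1%.  A false positive is counted per sequence: a random
sequence is one FP as soon as any family exceeds the threshold.
Thresholds for intermediate lengths are interpolated linearly in
log2(length) and clamped flat outside the calibrated range.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np

#: Calibrated length spectrum (aa).
DEFAULT_LENGTHS = (32, 64, 128, 256, 512, 1024)

#: Named FPR levels: default = most specific, sensitive = alternative.
DEFAULT_LEVELS = {"default": 0.001, "sensitive": 0.01}

#: Random sequences simulated per length.
DEFAULT_N_RANDOM = 100_000


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Amino-acid emission probabilities for random-sequence generation."""

    letters: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if len(self.letters) != len(p):
            raise ValueError("letters and probs must have equal length")
        if np.any(p <= 0):
            raise ValueError("background probabilities must be positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def freq(self) -> dict[str, float]:
        return dict(zip(self.letters, self.probs))

    def rank_probs(self, alph) -> np.ndarray:
        """Probabilities reordered to the ranks of an alphabet ordering."""
        out = np.empty(20)
        for letter, p in zip(self.letters, self.probs):
            out[alph.rank[letter]] = p
        return out


def load_background(path) -> BackgroundFrequencies:
    """Read a 20-line letter/frequency text table (frequencies renormalised)."""
    letters, vals = [], []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            tok = ln.split()
            letters.append(tok[0].upper())
            vals.append(float(tok[1]))
    v = np.asarray(vals)
    return BackgroundFrequencies("".join(letters), v / v.sum())


def default_background() -> BackgroundFrequencies:
    """Bundled background table (Swiss-Prot composition statistics)."""
    ref = importlib.resources.files("mosaicmatch.data") / "background_frequencies.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_background(path)


def random_protein(length: int, bg: BackgroundFrequencies, rng: np.random.Generator) -> str:
    """One i.i.d. random protein of the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    idx = rng.choice(len(bg.letters), size=length, p=bg.probs)
    return "".join(bg.letters[i] for i in idx)


def random_protein_ranks(
    n: int, length: int, bg: BackgroundFrequencies, alph, rng: np.random.Generator
) -> np.ndarray:
    """(n, length) int8 batch of random proteins, already rank-encoded."""
    p = bg.rank_probs(alph)
    return rng.choice(20, size=(n, length), p=p).astype(np.int8)


@dataclass
class ThresholdTable:
    """Per-length, per-level calibrated score thresholds."""

    lengths: tuple
    levels: dict  # level name -> FPR
    thresholds: dict  # level name -> np.ndarray aligned with lengths
    n_random: int
    seed: int
    log2_lengths: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lengths = tuple(int(x) for x in self.lengths)
        if list(self.lengths) != sorted(self.lengths):
            raise ValueError("lengths must be increasing")
        self.log2_lengths = np.log2(np.asarray(self.lengths, dtype=float))
        for name in self.levels:
            t = np.asarray(self.thresholds[name], dtype=float)
            if len(t) != len(self.lengths):
                raise ValueError(f"threshold row {name!r} has wrong length")
            self.thresholds[name] = t
        # a stricter FPR must not have a lower threshold
        by_fpr = sorted(self.levels, key=lambda k: self.levels[k])
        for strict, loose in zip(by_fpr, by_fpr[1:]):
            if np.any(self.thresholds[strict] < self.thresholds[loose] - 1e-12):
                raise ValueError(
                    "thresholds must be non-increasing in FPR level at fixed length"
                )


def calibrate_thresholds(
    db,
    bg: BackgroundFrequencies | None = None,
    n_random: int = DEFAULT_N_RANDOM,
    lengths=DEFAULT_LENGTHS,
    levels: dict | None = None,
    seed: int = 0,
) -> ThresholdTable:
    """Empirical FPR calibration of per-length noise thresholds.

    For each length, ``n_random`` random proteins are classified and
    their maximum per-family mosaic scores collected (0 when a sequence
    matches nothing); the threshold of level ``f`` is the higher-order
    (1 - f) empirical quantile, so the realised FPR on the calibration
    sample is at most nominal.  Both levels share the same sample.
    """
    from .classify import batch_max_scores  # deferred: avoids an import cycle

    if bg is None:
        bg = default_background()
    if levels is None:
        levels = dict(DEFAULT_LEVELS)
    for name, f in levels.items():
        if not 0 < f <= 1:
            raise ValueError(f"level {name!r}: FPR must be in (0, 1]")
        if n_random < 1.0 / f:
            raise ValueError(
                f"level {name!r}: n_random={n_random} cannot resolve FPR {f} "
                f"(need at least {int(np.ceil(1.0 / f))} sequences)"
            )
    rng = np.random.default_rng(seed)
    alph = db.forward.alphabet
    rows = {name: [] for name in levels}
    for L in lengths:
        ranks = random_protein_ranks(n_random, int(L), bg, alph, rng)
        maxima = batch_max_scores(ranks, db)
        for name, f in levels.items():
            rows[name].append(float(np.quantile(maxima, 1.0 - f, method="higher")))
    for name, vals in rows.items():
        if np.any(np.diff(vals) < 0):
            # empirical expectation, not a contract: longer random sequences
            # accumulate more chance matches
            warnings.warn(
                f"thresholds for level {name!r} are not non-decreasing in "
                f"length: {vals}; consider a larger n_random",
                stacklevel=2,
            )
    return ThresholdTable(
        lengths=tuple(lengths),
        levels=dict(levels),
        thresholds={name: np.asarray(v) for name, v in rows.items()},
        n_random=int(n_random),
        seed=int(seed),
    )


def threshold_for_length(table: ThresholdTable, L: int, level: str = "default") -> float:
    """Threshold at an arbitrary length: exact on the grid, interpolated
    linearly in log2(L) between grid lengths, clamped flat outside."""
    if L < 1:
        raise ValueError("length must be >= 1")
    t = table.thresholds[level]
    if L <= table.lengths[0]:
        return float(t[0])
    if L >= table.lengths[-1]:
        return float(t[-1])
    x = np.log2(float(L))
    return float(np.interp(x, table.log2_lengths, t))


def save_threshold_table(table: ThresholdTable, path) -> None:
    """Serialise the table as a small tab-separated text file."""
    with open(path, "w") as fh:
        fh.write(f"# n_random={table.n_random} seed={table.seed}\n")
        fh.write("level\tfpr\t" + "\t".join(str(x) for x in table.lengths) + "\n")
        for name in sorted(table.levels):
            row = "\t".join(repr(float(v)) for v in table.thresholds[name])
            fh.write(f"{name}\t{table.levels[name]!r}\t{row}\n")


def load_threshold_table(path) -> ThresholdTable:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
        cols = fh.readline().rstrip("\n").split("\t")
        lengths = tuple(int(x) for x in cols[2:])
        levels, thresholds = {}, {}
        for ln in fh:
            tok = ln.rstrip("\n").split("\t")
            if not tok[0]:
                continue
            levels[tok[0]] = float(tok[1])
            thresholds[tok[0]] = np.array([float(x) for x in tok[2:]])
    return ThresholdTable(
        lengths, levels, thresholds, int(meta["n_random"]), int(meta["seed"])
    )
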