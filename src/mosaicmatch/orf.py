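"""ORF extraction from DNA queries and read-level classification modes.

An ORF here is a maximal stop-codon-free codon run of at least 60 nt in
any of the six reading frames, translated with the standard genetic
code.  No start codon is required: short metagenomic fragments rarely
contain gene starts, so read ends count as open run boundaries.  Codons
containing N translate to X, which downstream word extraction rejects
(the window is skipped, the run is not split).  Coordinates are 0-based
half-open on the forward strand in all outputs.

Two classification modes mirror the standard tool behaviour for DNA
reads: *short* mode translates and classifies every ORF and reports
only the highest-scoring significant family across the read; *normal*
mode optionally pre-filters ORFs with a codon-usage log-odds score
(disabled by default: without a coding codon-frequency table the filter
is a no-op) and reports all significant families per surviving ORF,
which matters for multidomain proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .calibrate import ThresholdTable
from .classify import predict

#: Minimum ORF length in nucleotides (inclusive).
MIN_ORF_NT = 60

_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class ORFRecord:
    """One translated ORF with forward-strand coordinates."""

    source_id: str
    frame: int  # +1, +2, +3, -1, -2, -3
    nt_start: int  # 0-based half-open on the forward strand
    nt_end: int
    protein: str

    def __post_init__(self) -> None:
        span = self.nt_end - self.nt_start
        if span % 3 != 0:
            raise ValueError("ORF span must be divisible by 3")
        if len(self.protein) != span // 3:
            raise ValueError("protein length must equal span / 3")
        if "*" in self.protein:
            raise ValueError("ORF protein must not contain a stop symbol")


@dataclass(frozen=True)
class DnaPrediction:
    """One reported family for a DNA read, with its ORF coordinates."""

    read_id: str
    family: str
    score: float
    frame: int
    nt_start: int
    nt_end: int


def _codon_values(seq: str) -> np.ndarray:
    """Map a nucleotide string to per-base codes (A,C,G,T -> 0..3, other -> 4)."""
    table = np.full(256, 4, dtype=np.int8)
    for i, c in enumerate("ACGT"):
        table[ord(c)] = i
        table[ord(c.lower())] = i
    raw = np.frombuffer(seq.encode("latin-1", errors="replace"), dtype=np.uint8)
    return table[raw]


_STOP_VALUES = frozenset(
    16 * "ACGT".index(c[0]) + 4 * "ACGT".index(c[1]) + "ACGT".index(c[2])
    for c in _STOP_CODONS
)


def find_orfs(dna: str, source_id: str = "", min_len: int = MIN_ORF_NT) -> list[ORFRecord]:
    """All maximal stop-free codon runs of >= ``min_len`` nt, six frames.

    Returns an empty list for sequences shorter than ``min_len``.
    Frames are scanned +1, +2, +3 on the forward strand and -1, -2, -3
    on the reverse complement (frame -1 starts at the last forward
    base); coordinates always refer to the forward strand.
    """
    L = len(dna)
    out: list[ORFRecord] = []
    if L < min_len:
        return out
    dna_u = dna.upper()
    for strand, seq in ((1, dna_u), (-1, str(Seq(dna_u).reverse_complement()))):
        base = _codon_values(seq)
        for off in (0, 1, 2):
            n_codons = (L - off) // 3
            if n_codons == 0:
                continue
            c = base[off : off + 3 * n_codons].reshape(n_codons, 3)
            vals = 16 * c[:, 0] + 4 * c[:, 1] + c[:, 2]
            ambiguous = (c >= 4).any(axis=1)
            is_stop = np.isin(vals, list(_STOP_VALUES)) & ~ambiguous
            stops = np.flatnonzero(is_stop)
            run_starts = np.r_[0, stops + 1]
            run_ends = np.r_[stops, n_codons]
            for cs, ce in zip(run_starts, run_ends):
                nt = 3 * (ce - cs)
                if nt < min_len:
                    continue
                s = off + 3 * cs
                e = off + 3 * ce
                protein = str(Seq(seq[s:e]).translate())
                if strand == 1:
                    nt_start, nt_end, frame = s, e, off + 1
                else:
                    nt_start, nt_end, frame = L - e, L - s, -(off + 1)
                out.append(ORFRecord(source_id, frame, nt_start, nt_end, protein))
    out.sort(key=lambda r: (r.nt_start, r.nt_end, r.frame))
    return out


@dataclass(frozen=True)
class CodonUsageFilter:
    """Log-odds ORF pre-filter against a coding codon-frequency table.

    The score of an ORF is the mean log(f_codon / uniform) over its
    codons; ORFs scoring below ``threshold`` are dropped.  With no
    frequency table the filter keeps everything (the uniform model makes
    the log-odds identically zero), which is the default behaviour.
    """

    codon_freq: dict | None = None
    threshold: float = 0.0

    def keep(self, dna: str, orf: ORFRecord) -> bool:
        if self.codon_freq is None:
            return True
        if orf.frame > 0:
            sub = dna[orf.nt_start : orf.nt_end].upper()
        else:
            sub = str(Seq(dna[orf.nt_start : orf.nt_end].upper()).reverse_complement())
        codons = [sub[i : i + 3] for i in range(0, len(sub), 3)]
        uniform = 1.0 / 61.0
        vals = [
            np.log(self.codon_freq.get(c, uniform) / uniform)
            for c in codons
            if set(c) <= set("ACGT")
        ]
        if not vals:
            return False
        return float(np.mean(vals)) >= self.threshold


def classify_dna(
    read_id: str,
    dna: str,
    db,
    thresholds: ThresholdTable | None = None,
    mode: str = "short",
    level: str = "default",
    codon_filter: CodonUsageFilter | None = None,
    min_len: int = MIN_ORF_NT,
) -> list[DnaPrediction]:
    """Classify one DNA read through its ORFs.

    Short mode: every ORF is classified; at most the single best
    significant family across all ORFs of the read is reported, with the
    winning ORF's coordinates (ties: longer ORF span first, then smaller
    family index).  Normal mode: ORFs surviving the codon-usage filter
    are classified and *all* significant families per ORF are reported.
    """
    if mode not in ("short", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    orfs = find_orfs(dna, read_id, min_len=min_len)
    if mode == "normal" and codon_filter is not None:
        orfs = [o for o in orfs if codon_filter.keep(dna, o)]
    fam_index = {name: i for i, name in enumerate(db.forward.family_names)}
    preds: list[DnaPrediction] = []
    for orf in orfs:
        per_orf_mode = "best" if mode == "short" else "all"
        for fam, score in predict(orf.protein, db, thresholds, level, per_orf_mode):
            preds.append(
                DnaPrediction(read_id, fam, score, orf.frame, orf.nt_start, orf.nt_end)
            )
    if mode == "short" and preds:
        preds.sort(
            key=lambda p: (-p.score, -(p.nt_end - p.nt_start), fam_index[p.family])
        )
        preds = preds[:1]
    return preds
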