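"""Synthetic protein families, simulated reads and evaluation metrics.

The generator emulates the property the classifier depends on: a
reference collection that represents the sequence variation within each
family.  Each family is an ancestor protein drawn i.i.d. from
background frequencies; members are copies of the ancestor with i.i.d.
substitutions (to a uniformly chosen *different* residue) at a fixed
per-site rate, so the empirical substitution fraction matches the
nominal rate.  A disjoint held-out set is generated the same way for
end-to-end recovery experiments.  DNA reads are sampled uniformly from
back-translated genes (uniform synonymous codons, no sequencing
errors), inheriting the gene's family label.

Evaluation follows the usual confusion counts on read labels:
TPR = TP / (TP + FN) and PPV = TP / (TP + FP), where a read predicted
with a family different from its annotation counts both as an FP and as
an FN for the missed annotation, and predictions on unannotated reads
count as FP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .calibrate import BackgroundFrequencies, default_background
from .dictionary import LabelledSequence


@dataclass
class FamilySpec:
    """Parameters of the synthetic family generator."""

    n_families: int = 10
    members_per_family: int = 50
    member_length: int = 300
    substitution_rate: float = 0.05
    n_heldout_per_family: int = 10
    background: BackgroundFrequencies | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.member_length < 18:
            raise ValueError("member_length must be at least the word length")


@dataclass(frozen=True)
class EvalCounts:
    """Confusion counts of a labelled read set."""

    TP: int
    FP: int
    FN: int

    @property
    def tpr(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else float("nan")

    @property
    def ppv(self) -> float | None:
        """Positive predictive value; None (reported as NA) when undefined."""
        return self.TP / (self.TP + self.FP) if (self.TP + self.FP) else None


def _mutate(residues: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` by a different residue."""
    out = residues.copy()
    hit = np.flatnonzero(rng.random(len(out)) < rate)
    if len(hit):
        # uniform over the 19 other residues
        shift = rng.integers(1, 20, size=len(hit))
        out[hit] = (out[hit] + shift) % 20
    return out


def generate_families(
    spec: FamilySpec,
) -> tuple[list[LabelledSequence], list[LabelledSequence]]:
    """Reference members plus a disjoint held-out set, reproducible by seed."""
    bg = spec.background or default_background()
    rng = np.random.default_rng(spec.seed)
    letters = bg.letters
    members: list[LabelledSequence] = []
    heldout: list[LabelledSequence] = []
    for f in range(spec.n_families):
        label = f"FAM{f:04d}"
        ancestor = rng.choice(20, size=spec.member_length, p=bg.probs)
        for m in range(spec.members_per_family):
            seq = _mutate(ancestor, spec.substitution_rate, rng)
            members.append(
                LabelledSequence(
                    f"{label}_m{m:03d}", label, "".join(letters[i] for i in seq)
                )
            )
        for m in range(spec.n_heldout_per_family):
            seq = _mutate(ancestor, spec.substitution_rate, rng)
            heldout.append(
                LabelledSequence(
                    f"{label}_h{m:03d}", label, "".join(letters[i] for i in seq)
                )
            )
    return members, heldout


_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """DNA for a protein with uniformly chosen synonymous codons."""
    parts = []
    for aa in protein:
        codons = _CODONS_BY_AA[aa]
        parts.append(codons[rng.integers(len(codons))])
    return "".join(parts)


def simulate_reads(
    genes: list[LabelledSequence],
    read_length: int,
    coverage: float = 2.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[LabelledSequence], dict[str, str]]:
    """Uniform random fragments of labelled genes at a target coverage.

    ``genes`` holds DNA; each gene contributes ceil(coverage * len /
    read_length) reads with uniform start positions.  Returns the reads
    and a truth table read id -> family label.  No sequencing errors are
    introduced.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    reads: list[LabelledSequence] = []
    truth: dict[str, str] = {}
    for gene in genes:
        L = len(gene.residues)
        if L < read_length:
            raise ValueError(f"gene {gene.id!r} shorter than the read length")
        # stochastic rounding keeps the expected total read bases at
        # coverage * gene length
        target = coverage * L / read_length
        n_reads = int(target) + int(rng.random() < (target - int(target)))
        starts = rng.integers(0, L - read_length + 1, size=n_reads)
        for r, s in enumerate(starts):
            rid = f"{gene.id}_r{r:04d}"
            reads.append(
                LabelledSequence(rid, gene.label, gene.residues[s : s + read_length])
            )
            truth[rid] = gene.label
    return reads, truth


def evaluate(
    predictions: dict[str, str | None], truth: dict[str, str | None]
) -> EvalCounts:
    """Confusion counts of per-read best-family predictions.

    ``truth`` maps read id -> annotated family (None for negative
    reads); ``predictions`` maps read id -> predicted family (missing or
    None = no prediction).  A correct prediction is a TP; an annotated
    read without a prediction is an FN; a prediction differing from the
    annotation is an FP (and the missed annotation an FN); a prediction
    on a negative read is an FP.
    """
    unknown = set(predictions) - set(truth)
    if unknown:
        raise ValueError(f"predictions for ids absent from truth: {sorted(unknown)[:5]}")
    tp = fp = fn = 0
    for rid, annotated in truth.items():
        pred = predictions.get(rid)
        if annotated is not None:
            if pred == annotated:
                tp += 1
            else:
                fn += 1
                if pred is not None:
                    fp += 1
        elif pred is not None:
            fp += 1
    return EvalCounts(tp, fp, fn)
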