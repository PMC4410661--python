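# Methods

This note documents the model, the numerical choices and the
limitations of the `mosaicmatch` implementation, in the order the
pipeline runs.

## Word dictionary

Reference proteins are decomposed into all overlapping words of
`k = 18` residues (stride 1).  Words containing any residue outside the
20-letter alphabet — ambiguity codes (X/B/Z/U), stops, gaps, or
lowercase (pre-masked) residues — are skipped entirely rather than
substituted: a wrong residue would place the word at an unrelated
dictionary position.  The optional built-in low-complexity masker
computes Shannon entropy of the residue composition in a sliding
12-residue window and masks windows below 2.2 bits; it is a simple
entropy filter, deliberately transparent, and users who want a specific
masking behaviour can supply pre-masked FASTA (lowercase = masked),
which is honoured unconditionally.

Words are encoded order-preservingly: the first residue is the most
significant base-20 digit, so numeric order of `(prefix, suffix)` code
pairs equals lexicographic order under the permuted alphabet.  The
12-mer suffix fits a 64-bit unsigned integer (12·log₂20 ≈ 51.9 bits);
the hexamer prefix is kept in a separate block table.  The prefix table
is stored sparsely (sorted occupied prefix codes plus offsets) rather
than as a dense 20⁶ array, so toy databases stay small; the lookup
contract is unchanged.

Pruning proceeds in this order: (1) identical (word, label) pairs
collapse; (2) words carrying two or more distinct family labels are
removed unconditionally, regardless of label frequencies; (3) singleton
words — label differing from both sorted neighbours; boundary words
compare against their single neighbour, and a one-word dictionary is
kept — are *flagged* in a single pass over the original sorted order
and removed only after PSSM training.  The single pass does not
cascade: words whose same-label neighbour is later removed are not
re-flagged.  This still guarantees that after removal every kept word
retains an adjacent same-label neighbour, because a neighbour sharing a
kept word's label can itself never be flagged.

### Evolutionary alphabet ordering

The shipped alphabet permutation `ATSPGNDEQKRHYWFMLIVC` is a fixed
constant used by every downstream module; it is *not* recomputed at
build time, so databases are bit-stable.  For user-supplied scoring
matrices the package provides the full machinery: column-cosine
distances `d_ij = 1 − sᵢᵀsⱼ/(‖sᵢ‖‖sⱼ‖)` and a shortest-cyclic-path
solver (exact Held–Karp dynamic programming for alphabets of ≤ 12
letters, used in testing; nearest-neighbour construction with 2-opt
refinement and a fixed sweep budget for 20 letters, guaranteed no worse
than the identity ordering).  A cyclic tour has 2n equivalent writings;
the returned ordering is canonicalised to start at the alphabetically
smallest letter with the direction that puts the smaller of its two
tour neighbours second, making results deterministic.

## PSSM learning

Each adjacent pair of dictionary words is a training example with
target +1 (same family: a correct nearest-neighbour match) or −1.
Features are one-hot substitution indicators over the 12 suffix
positions (12 × 400 = 4800 parameters, no intercept); the prefix is not
scored because sorting makes leading positions nearly always identical
between neighbours.  The training set contains every pair with at
least one *mixed* endpoint — a location whose two incident pairs have
opposite signs — which concentrates training on family boundaries;
all remaining pairs validate the regularisation strength λ by
sign-agreement accuracy (prediction 0 counts as negative; with an
empty validation set, training accuracy is the fallback; on accuracy
ties the smallest λ wins).  Singleton words are still present at this
stage and supply negative examples.

The ridge problem is solved on the Gram matrix of the active features
only (inactive one-hot columns have exactly zero weight), with one
eigendecomposition shared across the whole λ grid — the default grid is
10 points log-spaced in [10⁻², 10⁴], spanning the shrinkage regimes for
counts-scale features.  Above 10⁶ training pairs the solver switches to
conjugate gradients (tolerance 10⁻⁸); both paths are oracle-checked
against dense normal equations.  Matrices are oriented query-in-rows
(training: earlier word = row) and are not symmetrised.  The
reverse-direction PSSM set is trained on the reverse dictionary by the
identical procedure and stored separately.

## Classification and mosaic score

Each valid query window is looked up forward and residue-reversed.  An
exact hit is scored against the matched word alone (its diagonal
entries); otherwise the one or two flanking words are used — a shared
label yields one match with the per-position maximum of the two score
vectors, distinct labels yield one match per label.  A query whose
hexamer prefix block is empty falls through to its insertion position
in the global sorted array, so the flanking words of adjacent blocks
are consulted (rather than declaring no match).  Reverse matches cover
the *first* 12 residues of the original window: the reversed word's
suffix position j maps back to window offset 11 − j.

The per-family mosaic total takes, at each residue covered by at least
one match of that family in either direction, the maximum positional
score, and sums over the sequence.  Uncovered residues contribute zero;
negative learned scores are kept as-is, so covering new residues can
lower a family's total (the per-residue maximum is only monotone on
residues already covered).  A family appears in the result only if it
achieved at least one word match.  In best-hit mode, score ties break
towards the smaller family index.

## Threshold calibration

Prediction requires the mosaic total to exceed a noise threshold
calibrated per database on random proteins with i.i.d. residues drawn
from a bundled background frequency table (Swiss-Prot composition
statistics; a custom 20-line table can be supplied).  The false
positive rate is defined per sequence: one random sequence counts as
one false positive as soon as *any* family exceeds the threshold —
a per-family definition would scale with database size.

Thresholds are the higher (conservative) empirical order statistic of
the per-sequence maximum family score at quantile 1 − f, so the
realised FPR on the calibration sample is at most nominal; both levels
(default f = 0.1 %, sensitive f = 1 %) share the same sample per
length.  The default sample size is 100 000 sequences per length
(≈ 100 expected exceedances at the 0.1 % level); calibration refuses
any f that the sample cannot resolve (n < 1/f).  The standard length
spectrum is 32–1024 aa in octaves; intermediate lengths are
interpolated linearly in log₂(length) — the grid is geometric, so
linear-in-length interpolation would systematically overshoot — and
clamped flat outside the calibrated range.  Thresholds are empirically
non-decreasing in length on synthetic databases (longer random
sequences accumulate more chance matches); a violation raises a
warning, not an error.

## DNA input

An ORF is a maximal stop-codon-free codon run of at least 60 nt
(inclusive — the boundary between "at least 60" and "> 60" in common
usage is resolved inclusively here) in any of the six frames, with no
start-codon requirement: metagenomic fragments rarely contain gene
starts, and read ends count as open boundaries.  Codons containing N
translate to X, which word extraction later rejects without splitting
the run; ambiguous codons that could be stops (e.g. TAN) are treated
as non-stops.  Coordinates are 0-based half-open on the forward strand
everywhere.  Short-read mode classifies every ORF and reports at most
the best significant family per read (ties: longer ORF, then smaller
family index); normal mode reports all significant families per ORF.
The optional codon-usage ORF pre-filter is a transparent mean log-odds
score of codon frequencies against a uniform model and is disabled by
default (with no codon table it is a no-op); it is a speed device, not
part of the classification model.

## Synthetic data and what it shows

The generator draws one ancestor protein per family i.i.d. from the
background frequencies and derives members by substituting each site
with the nominal rate, to a uniformly chosen *different* residue (so
the realised substitution fraction matches the rate).  Defaults are
10 families × 50 members × 300 aa at a 5 % substitution rate.  Reads
are sampled uniformly from back-translated genes (uniform synonymous
codons) at a target coverage with stochastic rounding of the per-gene
read count, without sequencing errors or indels — the classifier has
no gap model, so substitution stress is the relevant axis.

This emulates the one property the classifier needs from a reference
collection: families represented by many diverged members.  It does
not emulate real protein structure — no conserved motifs, no
low-complexity regions, no shared domains between families, no family
size imbalance, and family separation is far cleaner than between
homologous Pfam families.  Passing the end-to-end recovery bar
(TPR ≥ 0.9, PPV ≥ 0.95 on held-out mutated members) therefore
demonstrates that the machinery works as specified, not that those
rates transfer to real annotation tasks; the false-positive-rate
calibration checks, by contrast, are distribution-free per-sequence
statements and do transfer.

## Problem sizes and reproducibility

The acceptance computation uses the full study conditions: a database
from 500 × 300 aa references (~1.4 × 10⁵ words per direction) and
2 × 100 000 random 128-aa sequences for calibration and independent
validation; classification is vectorised (batched binary search and
gather-based PSSM scoring), so the whole run takes minutes on one CPU.
All randomness flows through seeded numpy generators: the same seed
reproduces databases bit-identically (serialisation uses sorted JSON
metadata and raw little-endian arrays) and classification output
byte-identically, regardless of the `--threads` setting, which is
accepted for interface compatibility while the implementation remains
a single vectorised process.

## Known limitations

- No E-values or analytic score statistics; significance is purely the
  empirical threshold.
- No gap model: indel-rich divergence will break word matches.
- Exact SEG masking is not reproduced; the entropy masker is an
  approximation and masking choices change the dictionary.
- Alternative genetic codes are not supported for ORF translation.
- Databases are rebuilt, not incrementally updated.
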