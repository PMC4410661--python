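"""Database bundle: build pipeline, on-disk layout, portable archive.

A database directory contains a text metadata file plus raw
little-endian arrays for the two word dictionaries (forward and
reverse), the two PSSM sets and the calibrated threshold table:

    meta.json            format version, word shape, alphabet, family
                         table, chosen lambdas, build statistics
    forward.suffixes     uint64   sorted suffix codes
    forward.labels       uint32   family index per word
    forward.prefix_keys  uint32   occupied hexamer prefixes
    forward.prefix_offsets int64  block boundaries (len = keys + 1)
    forward.pssm         float64  l x 20 x 20 scoring matrices
    reverse.*            same layout for the reverse dictionary
    thresholds.tsv       calibrated noise thresholds (text)
    background.tsv       background frequencies used for calibration

Identical content produces identical bytes, so a rebuild with the same
inputs and seed is bit-reproducible.  ``export_archive`` packs the
directory into a single portable uncompressed tar with normalised
metadata; ``import_archive`` restores it bit-exactly.
"""

from __future__ import annotations

import io
import json
import tarfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import AlphabetOrdering, DEFAULT_ALPHABET, DEFAULT_SHAPE, WordShape
from .calibrate import (
    BackgroundFrequencies,
    DEFAULT_LENGTHS,
    DEFAULT_LEVELS,
    DEFAULT_N_RANDOM,
    ThresholdTable,
    calibrate_thresholds,
    default_background,
    load_background,
    load_threshold_table,
    save_threshold_table,
)
from .dictionary import (
    LabelledSequence,
    WordDictionary,
    build_from_sequences,
    remove_singletons,
)
from .pssm import DEFAULT_LAMBDA_GRID, PSSMSet, fit, make_training_split

FORMAT_VERSION = 1


@dataclass
class Database:
    """Everything needed to classify queries."""

    forward: WordDictionary
    reverse: WordDictionary
    pssm_forward: PSSMSet
    pssm_reverse: PSSMSet
    thresholds: ThresholdTable | None = None
    background: BackgroundFrequencies | None = None
    stats: dict | None = None


def build_database(
    seqs: list[LabelledSequence],
    shape: WordShape = DEFAULT_SHAPE,
    alph: AlphabetOrdering = DEFAULT_ALPHABET,
    masker: str = "entropy",
    lambda_grid=DEFAULT_LAMBDA_GRID,
    calibrate: bool = True,
    bg: BackgroundFrequencies | None = None,
    n_random: int = DEFAULT_N_RANDOM,
    lengths=DEFAULT_LENGTHS,
    levels: dict | None = None,
    seed: int = 0,
) -> Database:
    """Full build: extract -> prune -> train PSSMs -> drop singletons
    -> calibrate.

    PSSM training runs on the dictionaries *with* singleton words
    (they supply negative examples); singletons are removed afterwards
    and thresholds are calibrated against the final dictionaries.
    """
    if not seqs:
        raise ValueError("no input sequences")
    family_names = sorted({s.label for s in seqs})
    stats: dict = {"n_sequences": len(seqs), "n_families": len(family_names)}
    if bg is None:
        bg = default_background()

    pair = {}
    for direction in ("forward", "reverse"):
        d_raw, d_stats = build_from_sequences(
            seqs, shape, alph, masker, direction, family_names
        )
        split = make_training_split(d_raw)
        pssm, diag = fit(split, lambda_grid, direction, return_diagnostics=True)
        d_final = remove_singletons(d_raw)
        d_stats["singletons_removed"] = d_raw.n_words - d_final.n_words
        d_stats["lambda"] = pssm.lam
        d_stats["n_train_pairs"] = diag["n_train"]
        d_stats["n_validation_pairs"] = diag["n_validation"]
        d_stats["validation_accuracy"] = float(np.max(diag["validation_accuracy"]))
        stats[direction] = d_stats
        pair[direction] = (d_final, pssm)

    db = Database(
        forward=pair["forward"][0],
        reverse=pair["reverse"][0],
        pssm_forward=pair["forward"][1],
        pssm_reverse=pair["reverse"][1],
        background=bg,
        stats=stats,
    )
    if calibrate:
        db.thresholds = calibrate_thresholds(
            db, bg, n_random=n_random, lengths=lengths, levels=levels, seed=seed
        )
        stats["calibration"] = {
            "n_random": int(n_random),
            "lengths": [int(x) for x in lengths],
            "seed": int(seed),
        }
    return db


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _save_dictionary(d: WordDictionary, out: Path, stem: str) -> None:
    d.suffixes.astype("<u8").tofile(out / f"{stem}.suffixes")
    d.labels.astype("<u4").tofile(out / f"{stem}.labels")
    d.prefix_keys.astype("<u4").tofile(out / f"{stem}.prefix_keys")
    d.prefix_offsets.astype("<i8").tofile(out / f"{stem}.prefix_offsets")


def _load_dictionary(
    src: Path, stem: str, shape: WordShape, alph: AlphabetOrdering,
    family_names: list[str], direction: str,
) -> WordDictionary:
    suffixes = np.fromfile(src / f"{stem}.suffixes", dtype="<u8").astype(np.uint64)
    labels = np.fromfile(src / f"{stem}.labels", dtype="<u4").astype(np.uint32)
    keys = np.fromfile(src / f"{stem}.prefix_keys", dtype="<u4").astype(np.uint32)
    offsets = np.fromfile(src / f"{stem}.prefix_offsets", dtype="<i8").astype(np.int64)
    # reconstruct the per-entry prefix array from the block table
    prefixes = np.repeat(keys, np.diff(offsets)).astype(np.uint32)
    return WordDictionary(
        shape, alph, suffixes, labels, prefixes, keys, offsets,
        family_names, direction, None,
    )


def save_database(db: Database, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": FORMAT_VERSION,
        "word_length": db.forward.shape.word_length,
        "prefix_length": db.forward.shape.prefix_length,
        "suffix_length": db.forward.shape.suffix_length,
        "alphabet": db.forward.alphabet.order,
        "family_names": db.forward.family_names,
        "lambda_forward": db.pssm_forward.lam,
        "lambda_reverse": db.pssm_reverse.lam,
        "stats": db.stats or {},
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    _save_dictionary(db.forward, out, "forward")
    _save_dictionary(db.reverse, out, "reverse")
    db.pssm_forward.matrices.astype("<f8").tofile(out / "forward.pssm")
    db.pssm_reverse.matrices.astype("<f8").tofile(out / "reverse.pssm")
    if db.thresholds is not None:
        save_threshold_table(db.thresholds, out / "thresholds.tsv")
    if db.background is not None:
        with open(out / "background.tsv", "w") as fh:
            for letter, p in zip(db.background.letters, db.background.probs):
                fh.write(f"{letter}\t{float(p)!r}\n")


def load_database(src_dir) -> Database:
    src = Path(src_dir)
    meta_path = src / "meta.json"
    if not meta_path.exists():
        raise ValueError(f"{src}: not a database directory (meta.json missing)")
    meta = json.loads(meta_path.read_text())
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"{src}: database format version {version!r} is not supported by "
            f"this build (expected {FORMAT_VERSION}); re-create the database"
        )
    shape = WordShape(
        meta["word_length"], meta["prefix_length"], meta["suffix_length"]
    )
    alph = AlphabetOrdering(meta["alphabet"])
    fams = list(meta["family_names"])
    l = shape.suffix_length
    fwd = _load_dictionary(src, "forward", shape, alph, fams, "forward")
    rev = _load_dictionary(src, "reverse", shape, alph, fams, "reverse")
    pssm_f = PSSMSet(
        np.fromfile(src / "forward.pssm", dtype="<f8").reshape(l, 20, 20),
        meta["lambda_forward"], "forward",
    )
    pssm_r = PSSMSet(
        np.fromfile(src / "reverse.pssm", dtype="<f8").reshape(l, 20, 20),
        meta["lambda_reverse"], "reverse",
    )
    thresholds = None
    if (src / "thresholds.tsv").exists():
        thresholds = load_threshold_table(src / "thresholds.tsv")
    background = None
    if (src / "background.tsv").exists():
        background = load_background(src / "background.tsv")
    return Database(fwd, rev, pssm_f, pssm_r, thresholds, background, meta["stats"])


# ---------------------------------------------------------------------------
# Portable archive
# ---------------------------------------------------------------------------

def export_archive(db_dir, archive_path) -> None:
    """Pack a database directory into one portable uncompressed tar.

    Member order, ownership and timestamps are normalised so identical
    directories always produce identical archives.
    """
    src = Path(db_dir)
    if not (src / "meta.json").exists():
        raise ValueError(f"{src}: not a database directory")
    with tarfile.open(archive_path, "w") as tar:
        for path in sorted(p for p in src.iterdir() if p.is_file()):
            info = tarfile.TarInfo(name=path.name)
            data = path.read_bytes()
            info.size = len(data)
            info.mtime = 0
            info.uid = info.gid = 0
            info.uname = info.gname = ""
            info.mode = 0o644
            tar.addfile(info, io.BytesIO(data))


def import_archive(archive_path, out_dir) -> None:
    """Restore a database directory from a portable archive, bit-exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with tarfile.open(archive_path, "r") as tar:
        for member in tar.getmembers():
            name = Path(member.name).name  # flat archive; refuse path tricks
            if not member.isfile():
                continue
            with tar.extractfile(member) as fh:
                (out / name).write_bytes(fh.read())
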