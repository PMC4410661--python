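import numpy as np
import pytest

import mosaicmatch as mm
from mosaicmatch.database import Database
from mosaicmatch.pssm import PSSMSet


@pytest.fixture(scope="session")
def tiny_spec():
    return mm.FamilySpec(
        n_families=5,
        members_per_family=10,
        member_length=100,
        substitution_rate=0.05,
        n_heldout_per_family=4,
        seed=1,
    )


@pytest.fixture(scope="session")
def tiny_families(tiny_spec):
    return mm.generate_families(tiny_spec)


@pytest.fixture(scope="session")
def tiny_db(tiny_families):
    """Small trained + calibrated database shared across the session."""
    members, _ = tiny_families
    return mm.build_database(
        members,
        masker="none",
        calibrate=True,
        n_random=2000,
        lengths=(32, 64, 128),
        seed=2,
    )


def identity_pssm(direction: str) -> PSSMSet:
    """Diagonal scoring: 1 for a conserved residue, 0 for any substitution."""
    mats = np.zeros((12, 20, 20))
    mats[:, np.arange(20), np.arange(20)] = 1.0
    return PSSMSet(mats, lam=1.0, direction=direction)


def make_identity_db(seqs, masker: str = "none") -> Database:
    """Database with untrained identity PSSMs, for hand-checkable scoring.

    Singleton pruning is skipped: these fixtures use few random words,
    which are almost all singletons in the sorted order.
    """
    fwd, _ = mm.build_from_sequences(seqs, masker=masker, direction="forward")
    rev, _ = mm.build_from_sequences(seqs, masker=masker, direction="reverse")
    return Database(
        forward=fwd,
        reverse=rev,
        pssm_forward=identity_pssm("forward"),
        pssm_reverse=identity_pssm("reverse"),
    )


def random_protein_string(rng, length, letters="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(letters[i] for i in rng.integers(0, 20, size=length))
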