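import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from pahtrait import synth
from pahtrait.refdb import ReferenceDatabase, ReferenceSequence

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_family(seed: int, size: int = 8, length: int = 120, rate: float = 0.10):
    return synth.generate_family(
        synth.FamilyGeneratorConfig(
            family_size=size, ancestor_length=length, substitution_rate=rate,
            indel_rate=0.01, seed=seed,
        )
    )


@pytest.fixture(scope="session")
def small_db() -> ReferenceDatabase:
    """Three compact synthetic families (fast unit-test database)."""
    seqs = []
    for i, fam in enumerate(("nahAc", "nahE", "nidA")):
        truth = make_family(seed=100 + i)
        seqs.extend(
            ReferenceSequence(f"{fam}_{j:02d}", fam, "synthetic organism", "seed", s)
            for j, s in enumerate(truth.members)
        )
    return ReferenceDatabase(sequences=seqs, version="test")


@pytest.fixture(scope="session")
def small_models(small_db):
    from pahtrait.calibrate import calibrate_all

    return calibrate_all(small_db, seed=5, n_shuffles=20)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
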