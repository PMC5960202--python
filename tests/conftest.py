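from pathlib import Path

import numpy as np
import pytest

from foldbridge.io_formats import SequenceRecord
from foldbridge.profiles import FamilyProfile, ProfileColumn

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def tiny_alignment() -> list[SequenceRecord]:
    return [
        SequenceRecord("s1", "ACDEFG"),
        SequenceRecord("s2", "ACDEFG"),
        SequenceRecord("s3", "ACDEYG"),
    ]


def make_profile(freq_rows, family_id="p") -> FamilyProfile:
    """Build a FamilyProfile from explicit per-column frequency vectors."""
    cols = []
    for row in freq_rows:
        f = np.asarray(row, dtype=float)
        f = f / f.sum()
        cols.append(ProfileColumn(freqs=f, gap_fraction=0.0, n_eff=1.0))
    return FamilyProfile(family_id=family_id, columns=tuple(cols))


def random_profile(rng: np.random.Generator, length: int, conc: float = 0.5) -> FamilyProfile:
    """A profile with Dirichlet-distributed column frequencies."""
    rows = rng.dirichlet(np.full(20, conc), size=length)
    return make_profile(rows)


def delta_column(residue_index: int) -> np.ndarray:
    f = np.zeros(20)
    f[residue_index] = 1.0
    return f
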