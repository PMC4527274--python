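import numpy as np
import pytest

from cblkit.core_io import AMINO_ACIDS, ProteinRecord
from cblkit.synthetic_data import FamilySpec, make_family


def canonical_hand_window() -> str:
    """A minimal 36-aa window satisfying the strict EF-hand rule.

    Oxygen donors at loop positions 1, 3 and 12 (window 13, 15, 24),
    Asp/Glu at window positions 14 and 22; everything else alanine.
    """
    win = ["A"] * 36
    win[12] = "S"   # loop 1
    win[13] = "D"   # key position 14
    win[14] = "T"   # loop 3
    win[21] = "E"   # key position 22
    win[23] = "D"   # loop 12, bidentate
    return "".join(win)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture(scope="session")
def default_family():
    """One synthetic CBL-like family under the default study conditions."""
    return make_family(FamilySpec(seed=42))


@pytest.fixture
def simple_records():
    return [
        ProteinRecord(id="a", sequence="MGCFH"),
        ProteinRecord(id="b", sequence="MGCYH"),
    ]
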