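import itertools

import pytest

from taggimatrix.demux import SampleSheet
from taggimatrix.index_kit import load_default_set
from taggimatrix.primer_forge import LocusPrimer, build_primer_panel, plate_layout

PLETH_F = "AAAAAAGTCAGGTCAAGG"
PLETH_R = "GGTGACGGGCGGTGTGTG"


def dp_levenshtein(a: str, b: str) -> int:
    """Independent dynamic-programming edit-distance oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@pytest.fixture(scope="session")
def default_set():
    return load_default_set()


@pytest.fixture(scope="session")
def pleth_primers():
    return (
        LocusPrimer("Pleth_12S_F", PLETH_F, "forward"),
        LocusPrimer("Pleth_12S_R", PLETH_R, "reverse"),
    )


@pytest.fixture(scope="session")
def truseq_panel(default_set, pleth_primers):
    fwd, rev = pleth_primers
    return build_primer_panel(fwd, rev, "TruSeq", default_set)


@pytest.fixture(scope="session")
def full_plate_sheet(default_set, truseq_panel):
    """96-entry samplesheet covering every forward x reverse tag combination."""
    plate = plate_layout(truseq_panel)
    entries = {
        plate.wells[f"{row}{col}"]: f"S_{row}{col}"
        for row, col in itertools.product("ABCDEFGH", range(1, 13))
    }
    return SampleSheet(
        entries, default_set, forward_primer=PLETH_F, reverse_primer=PLETH_R
    )


@pytest.fixture(scope="session")
def diagonal_sheet(default_set):
    """Sheet using only the matched-label diagonal (A,1), (B,2), ... (H,8)."""
    entries = {
        (fwd, str(i + 1)): f"D{i + 1:02d}" for i, fwd in enumerate("ABCDEFGH")
    }
    return SampleSheet(
        entries, default_set, forward_primer=PLETH_F, reverse_primer=PLETH_R
    )
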