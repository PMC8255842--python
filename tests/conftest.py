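import numpy as np
import pandas as pd
import pytest

from mirscreen.seeds import MIR194, MatureMiRNA, TranscriptModel, build_seed_patterns


@pytest.fixture(scope="session")
def mir194() -> MatureMiRNA:
    return MIR194


@pytest.fixture(scope="session")
def mir194_patterns(mir194) -> dict:
    return build_seed_patterns(mir194)


@pytest.fixture
def toy_transcript() -> TranscriptModel:
    """40-nt coding toy: 5'UTR [0,5), CDS [5,25), 3'UTR [25,40)."""
    return TranscriptModel(
        "TX1", "GENE1", "C" * 5 + "G" * 20 + "C" * 15, cds_start=5, cds_end=25
    )


@pytest.fixture
def small_expression() -> tuple[pd.DataFrame, pd.DataFrame]:
    """4 genes x 2 cell lines x (mimic, NC); hand-chosen values."""
    expr = pd.DataFrame(
        {
            "A_mimic": [10.0, 5.0, 3.0, 100.0],
            "A_NC": [10.0, 10.0, 1.0, 100.0],
            "B_mimic": [10.0, 4.0, 3.0, 50.0],
            "B_NC": [10.0, 10.0, 1.0, 100.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["A_mimic", "A_NC", "B_mimic", "B_NC"],
            "cell_line": ["A", "A", "B", "B"],
            "condition": ["mimic", "NC", "mimic", "NC"],
        }
    )
    return expr, meta


def random_mirna(rng: np.random.Generator, length: int = 22) -> MatureMiRNA:
    seq = "".join(rng.choice(list("ACGU"), size=length))
    return MatureMiRNA("rand", seq)


def random_transcript(rng: np.random.Generator, max_len: int = 500) -> TranscriptModel:
    length = int(rng.integers(20, max_len + 1))
    seq = "".join(rng.choice(list("ACGU"), size=length))
    cds_start = int(rng.integers(0, length // 3))
    cds_end = int(rng.integers(cds_start + 1, length + 1))
    return TranscriptModel("tx", "g", seq, cds_start, cds_end)
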