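import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from g4pipe.seqio import TranscriptRecord


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def small_transcripts() -> list[TranscriptRecord]:
    return [
        TranscriptRecord("u1", "ATGC" * 75),            # 300 bp
        TranscriptRecord("u2", "GGGAGGGAGGGAGGG" + "ACT" * 95),
        TranscriptRecord("u3", "TTA" * 200),            # 600 bp
    ]
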