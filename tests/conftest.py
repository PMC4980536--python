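import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from targetprofiler.similarity import EvalueParams

DNA = "ACGT"


def simple_matrix(alphabet: str = DNA, match: float = 1.0,
                  mismatch: float = -1.0) -> dict:
    return {
        (a, b): (match if a == b else mismatch)
        for a in alphabet for b in alphabet
    }


def uniform_background(alphabet: str = DNA) -> dict:
    return {a: 1.0 / len(alphabet) for a in alphabet}


@pytest.fixture(scope="session")
def blosum_params() -> EvalueParams:
    """BLOSUM62 / gap 11+1 scheme with lambda and K computed once."""
    params = EvalueParams()
    params.lambda_, params.kappa  # warm the cache
    return params


@pytest.fixture()
def simple_params() -> EvalueParams:
    """Match +1 / mismatch -1 over a uniform 4-letter alphabet, gaps 2+1."""
    return EvalueParams(
        matrix=simple_matrix(), background=uniform_background(),
        gap_open=2.0, gap_extend=1.0,
    )
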