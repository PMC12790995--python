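import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from paranome.simulate import simulate_family, simulate_transcripts


@pytest.fixture(scope="session")
def small_family():
    """6 paralogs, 4 samples, paralog-level divergence 10x allele level."""
    return simulate_family(
        ancestor_len=4_000,
        n_paralogs=6,
        inter_div=0.03,
        intra_div=0.003,
        seed=3,
        n_samples=4,
        flank=100,
        spacer=100,
    )


@pytest.fixture(scope="session")
def vntr_family():
    """Family with planted coding VNTRs for transcript/repeat analyses."""
    return simulate_family(
        ancestor_len=8_000,
        n_paralogs=8,
        inter_div=0.03,
        intra_div=0.001,
        seed=21,
        flank=100,
        spacer=100,
        vntr_units={"P3": (7, 6, 5), "P5": (9, 8, 7)},
    )


@pytest.fixture(scope="session")
def vntr_transcripts(vntr_family):
    return simulate_transcripts(vntr_family)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
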