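import numpy as np
import pytest

from iblopt.agent import SimulationConfig
from iblopt.memory import ActivationParams
from iblopt.streams import make_batch


@pytest.fixture(scope="session")
def batch100_seed1():
    """100 frozen replicate streams from master seed 1 (standard conditions)."""
    return make_batch(1, 100)


@pytest.fixture(scope="session")
def batches_3seeds():
    """100-replicate batches for master seeds 1..3."""
    return {seed: make_batch(seed, 100) for seed in (1, 2, 3)}


@pytest.fixture()
def mid_config():
    """A configuration in the well-learning parameter region."""
    return SimulationConfig(params=ActivationParams(tau=-3.14, P=20.0))


def random_memory(rng, n_chunks=30, max_round=40):
    """A randomized populated memory state, for retrieval-oracle tests."""
    from iblopt.memory import DeclarativeMemory, N_CHUNKS

    mem = DeclarativeMemory()
    idx = rng.choice(N_CHUNKS, size=n_chunks, replace=False)
    for i in idx:
        mem.populated[i] = True
        mem.t[i] = int(rng.integers(1, max_round + 1))
        mem.n[i] = int(rng.integers(1, 6))
    return mem
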