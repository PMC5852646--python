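import numpy as np
import pytest

from mprna.pool_design import DesignParams, assemble_pool
from mprna.simulate import SimConfig, simulate_counts


def random_seq(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def two_transcripts() -> dict[str, str]:
    return {"txA": random_seq(500, 11), "txB": random_seq(310, 12)}


@pytest.fixture(scope="session")
def small_pool(two_transcripts):
    return assemble_pool(two_transcripts, DesignParams(seed=3))


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated experiment reused across modules."""
    cfg = SimConfig(
        n_transcripts=2,
        transcript_length=(800, 800),
        reads_per_sample=2e5,
        seed=7,
    )
    manifest, counts, truth = simulate_counts(cfg)
    return cfg, manifest, counts, truth
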