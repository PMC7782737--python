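import numpy as np
import pytest

from lorcas import simulate as sim
from lorcas.io_core import PipelineConfig


@pytest.fixture(scope="session")
def small_genome():
    return sim.make_genome(60_000, seed=11)


@pytest.fixture(scope="session")
def noisy_readset(small_genome):
    """~20x of 15%-error reads over the small genome, with truth."""
    model = sim.ErrorModel(mean_rate=0.15)
    reads, truths = sim.sample_reads(
        small_genome, 20, (8_000, 3_000, 20_000), model, seed=13
    )
    return reads, truths, model


@pytest.fixture(scope="session")
def clean_readset(small_genome):
    """Noise-free reads (exact substrings of the genome)."""
    model = sim.ErrorModel.noiseless()
    reads, truths = sim.sample_reads(
        small_genome, 12, (8_000, 3_000, 20_000), model, seed=17
    )
    return reads, truths


@pytest.fixture()
def config():
    return PipelineConfig()


def random_pair(rng, n, rate, sub=0.4, ins=0.3, dele=0.3):
    """A sequence and a noisy copy with iid edits; returns code arrays."""
    a = rng.integers(0, 4, n).astype(np.uint8)
    out = []
    for x in a:
        r = rng.random()
        if r < rate * sub:
            out.append((x + rng.integers(1, 4)) % 4)
        elif r < rate * (sub + ins):
            out.append(rng.integers(0, 4))
            out.append(x)
        elif r < rate:
            pass
        else:
            out.append(x)
    return a, np.array(out, np.uint8)
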