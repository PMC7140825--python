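import numpy as np
import pytest

from dlohic.simulate import DESIGNS, SimParams, simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def hindiii_params():
    return SimParams(seed=7, counts={"valid": 2000, "self_ligation": 100,
                                     "re_ligation": 100, "heterodimer": 200,
                                     "no_linker": 100}, duplicate_rate=0.1)


@pytest.fixture(scope="session")
def hindiii_library(hindiii_params):
    """Default HindIII-design library: genome, reads, truth table."""
    genome = simulate_genome(hindiii_params)
    reads, truth = simulate_reads(hindiii_params, genome)
    return genome, reads, truth


@pytest.fixture(scope="session")
def small_genome():
    """5 kb single-chromosome random genome for brute-force comparisons."""
    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
    return {"chr1": seq}


@pytest.fixture(scope="session")
def msei_design():
    return DESIGNS["msei"]


@pytest.fixture(scope="session")
def hindiii_design():
    return DESIGNS["hindiii"]
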