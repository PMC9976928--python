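import numpy as np
import pytest

from passerpipe import make_ancestral_element, plant_family, random_genome


@pytest.fixture(scope="session")
def ancestor():
    return make_ancestral_element(seed=1)


@pytest.fixture(scope="session")
def small_genome():
    return random_genome(seed=2, lengths={"chr1": 120_000, "chr2": 60_000})


@pytest.fixture(scope="session")
def planted(ancestor):
    """Genome with 8 perfect (K=0) planted copies plus the truth table."""
    genome = random_genome(seed=3, lengths={"chr1": 250_000})
    return plant_family(genome, ancestor, [(0.0, 8, 1.0)], seed=4)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
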