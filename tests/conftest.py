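import numpy as np
import pytest

from epistasim import PenetranceModel, two_locus_example


@pytest.fixture
def example_model() -> PenetranceModel:
    """Two-locus pure, strict example model with MAFs 0.4/0.5 and K ≈ 0.614."""
    return two_locus_example()


def random_model(rng: np.random.Generator, max_loci: int = 3) -> PenetranceModel:
    """A random valid model: 1..max_loci loci, MAFs in (0.05, 0.5), uniform
    penetrances."""
    n = int(rng.integers(1, max_loci + 1))
    mafs = tuple(rng.uniform(0.05, 0.5, size=n))
    return PenetranceModel(mafs=mafs, penetrances=rng.uniform(0.0, 1.0, size=3**n))


@pytest.fixture
def random_model_factory():
    return random_model
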