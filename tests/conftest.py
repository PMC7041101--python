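import numpy as np
import pytest

from wgalign.genome import Genome

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int, alphabet: str = BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def toy_genome(rng) -> Genome:
    return Genome("toy", random_seq(rng, 100))


def mutate_at(seq: str, pos: int, base: str) -> str:
    """Substitute 1-based ``pos`` with ``base`` (must differ)."""
    assert seq[pos - 1] != base
    return seq[: pos - 1] + base + seq[pos:]
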