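import numpy as np
import pytest

from mirnaclust.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """10 families x 6 members, low noise — easy to recover."""
    spec = SyntheticSpec(
        n_families=10,
        family_size_range=(6, 6),
        substitution_rate=0.02,
        seed=7,
    )
    return generate(spec)


def random_rna(rng, length):
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=length)])
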