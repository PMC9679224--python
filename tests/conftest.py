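import numpy as np
import pytest

from coldadapt import synthetic


@pytest.fixture(scope="session")
def default_spec() -> synthetic.SyntheticSpec:
    return synthetic.SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def planted_genome(default_spec):
    """One synthetic species genome with truth tables (session-cached)."""
    asm, gff3, truth = synthetic.generate_genome(default_spec, "P_glacialis")
    return asm, gff3, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
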