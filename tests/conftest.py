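import numpy as np
import pytest

from lenscalcium import GeneratorConfig, generate_capsule


def small_config(**kw) -> GeneratorConfig:
    """Compact capsule used throughout the suite: quick but fully featured."""
    defaults = dict(n_cells=100, field_size=240.0, t_total=400.0,
                    t_stim=100.0, seed=0)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def capsule():
    """One deterministic synthetic capsule shared by read-only tests."""
    return generate_capsule(small_config(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
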