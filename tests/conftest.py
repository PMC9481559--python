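import pytest

from guideforge.pool import GenerationConstraints, generate_pool


@pytest.fixture(scope="session")
def small_pool():
    """Six annealed candidates under default constraints, fixed seed."""
    return generate_pool(GenerationConstraints(pool_size=6), rng_seed=11)
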