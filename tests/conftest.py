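import pytest

from selkie import SimulationConfig, make_genome


@pytest.fixture
def male_genome():
    """Two 4 Mb autosomes plus a 12 Mb X carrying a 3 Mb terminal PAR."""
    return make_genome(
        n_autosomes=2,
        autosome_lengths=[4_000_000, 4_000_000],
        x_length=12_000_000,
        par_length=3_000_000,
        sex="male",
    )


@pytest.fixture
def female_genome():
    return make_genome(
        n_autosomes=2,
        autosome_lengths=[4_000_000, 4_000_000],
        x_length=12_000_000,
        par_length=3_000_000,
        sex="female",
    )


@pytest.fixture
def sim_config():
    return SimulationConfig(mean_depth=30.0, seed=7)
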