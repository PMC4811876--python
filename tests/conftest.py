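import pytest

from grasfam import SimulationConfig, grapevine_gras_table
from grasfam.synthetic import simulate_family


@pytest.fixture(scope="session")
def table1():
    return grapevine_gras_table()


@pytest.fixture(scope="session")
def small_config():
    # small family: 5 subfamilies x 3 members, fast enough for unit tests
    return SimulationConfig(
        seed=11,
        n_subfamilies=5,
        members_per_subfamily=(3, 3),
        protein_length=(400, 450),
        n_tandem_arrays=1,
        n_segmental_pairs=1,
        lost_subfamilies=1,
        n_lineage_duplicates=1,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_family(small_config)
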