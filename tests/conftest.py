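import pytest

import tierplan as tp


@pytest.fixture(scope="session")
def schedule() -> tp.TierSchedule:
    return tp.load_tier_schedule()


@pytest.fixture(scope="session")
def small_config() -> tp.NetworkConfig:
    """A reduced country: 12 districts, 400 facilities, 12 CD4 labs."""
    return tp.NetworkConfig(
        n_districts=12,
        n_provinces=3,
        n_facilities=400,
        n_labs=12,
        n_general_labs=24,
        n_lab_free_districts=3,
        total_annual_tests=300_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_network(small_config):
    return tp.generate_network(small_config)


@pytest.fixture(scope="session")
def full_network():
    """The default country-scale network (seed 1)."""
    return tp.generate_network(tp.NetworkConfig(seed=1))


@pytest.fixture(scope="session")
def full_assignments(full_network, schedule):
    facilities, labs, _ = full_network
    return tp.assign_nearest(facilities, tp.cd4_labs(labs), schedule)
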