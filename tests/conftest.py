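import pytest

import beastsim as bs


@pytest.fixture(scope="session")
def schedule():
    return bs.make_stimulus_schedule(7)


@pytest.fixture(scope="session")
def default_params():
    return bs.AgentParams()


@pytest.fixture(scope="session")
def small_bank(schedule, default_params):
    return bs.build_bank(schedule, estimation_params=default_params, seed=11)


@pytest.fixture(scope="session")
def small_config():
    return bs.CohortConfig().scaled(40)


@pytest.fixture(scope="session")
def small_profiles(small_config):
    return bs.sample_cohort(small_config, seed=3)


@pytest.fixture(scope="session")
def small_trials(small_config, small_bank, small_profiles):
    return bs.simulate_experiment(small_config, small_bank, seed=5, profiles=small_profiles)


@pytest.fixture(scope="session")
def small_adjustments(small_trials):
    return bs.filter_valid(bs.compute_adjustments(small_trials), "omit")


@pytest.fixture(scope="session")
def small_summaries(small_adjustments):
    return bs.participant_summary(small_adjustments)
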