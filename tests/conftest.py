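import pytest

import predinfer as pi


@pytest.fixture(scope="session")
def task_config():
    return pi.TaskConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """30 default-effect subjects; shared across regression/metrics tests."""
    trials, subjects = pi.simulate_cohort(n_subjects=30, seed=2024)
    return trials, subjects


@pytest.fixture(scope="session")
def derived_trials(small_cohort):
    trials, _ = small_cohort
    return pi.apply_trial_exclusions(pi.derive_trials(trials))


@pytest.fixture(scope="session")
def analysis_table(derived_trials, small_cohort):
    _, subjects = small_cohort
    return pi.prepare_analysis_table(derived_trials, subjects, moderators=("AD", "CIT", "SW"))
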