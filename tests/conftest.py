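import pytest

from cascore import simulate_cohort, worked_example_cohort


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    """A mid-sized simulated cohort reused by read-only tests."""
    return simulate_cohort(n_women=800, seed=42)
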