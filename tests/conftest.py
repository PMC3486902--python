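import pytest

from iceffect import datasets
from iceffect.model import ICEModel


@pytest.fixture(scope="session")
def carrier_cases():
    cases, tallies = datasets.load_carrier_cases()
    return cases, tallies


@pytest.fixture(scope="session")
def control_groups():
    return datasets.load_control_groups()


@pytest.fixture(scope="session")
def study_results():
    """Fitted model on the packaged study tables (computed once)."""
    return ICEModel.from_study_tables().fit()
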