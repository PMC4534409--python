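import pytest

from aplbim import base_case_config
from aplbim.inputs import TransitionProbabilities


@pytest.fixture(scope="session")
def base_config():
    return base_case_config()


@pytest.fixture(scope="session")
def ato_probs(base_config):
    return base_config.regimens.ato_atra.transition_probabilities


@pytest.fixture(scope="session")
def atra_probs(base_config):
    return base_config.regimens.atra_chemo.transition_probabilities


@pytest.fixture
def no_transition_probs():
    return TransitionProbabilities(stable_to_event=0.0, stable_to_death=0.0, event_to_death=0.0)
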