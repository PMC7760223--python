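import warnings

import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from alidose.simulate import SimulationConfig  # noqa: E402


@pytest.fixture
def default_config():
    return SimulationConfig(seed=42)


@pytest.fixture
def single_condition_config():
    return SimulationConfig(seed=7, condition_truths={"exposure": 85.0})
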