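import numpy as np
import pytest

from intentprior.task_design import TaskConfig, generate_run


@pytest.fixture(scope="session")
def default_design():
    return generate_run(TaskConfig(seed=7))


@pytest.fixture(scope="session")
def social_design():
    return generate_run(TaskConfig(task_type="social", seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
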