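import pytest
from hypothesis import settings

import saltshift as ss

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tables():
    return ss.generate_fixtures()


@pytest.fixture(scope="session")
def model(tables):
    return ss.PMSLTModel(tables)


@pytest.fixture(scope="session")
def results_all(model):
    """Deterministic runs of all nine scenarios on the default fixture."""
    return model.run_many(range(1, 10))
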