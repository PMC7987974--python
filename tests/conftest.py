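import hypothesis
import pytest

import agaclust as ag

hypothesis.settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def model_protein():
    return ag.make_model_protein()


@pytest.fixture(scope="session")
def profile_setup():
    protein, clusters = ag.make_profile_protein()
    return protein, clusters


@pytest.fixture()
def config():
    return ag.SimConfig(n_ribosomes=1e8, seed=1)
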