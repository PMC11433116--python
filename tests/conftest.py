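import pytest

from markovcua import packaged_model, run_model


@pytest.fixture(scope="session")
def rare_model():
    return packaged_model("rare")


@pytest.fixture(scope="session")
def non_rare_model():
    return packaged_model("non_rare")


@pytest.fixture(scope="session")
def rare_result(rare_model):
    return run_model(rare_model)


@pytest.fixture(scope="session")
def non_rare_result(non_rare_model):
    return run_model(non_rare_model)
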