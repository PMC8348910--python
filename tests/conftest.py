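import pytest

from ergoforces import load_angle_graphs, load_thresholds, neutral_model


@pytest.fixture(scope="session")
def male_p50():
    return neutral_model("male", "P50")


@pytest.fixture(scope="session")
def female_p50():
    return neutral_model("female", "P50")


@pytest.fixture(scope="session")
def thresholds():
    return load_thresholds()


@pytest.fixture(scope="session")
def graphs():
    return load_angle_graphs()
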