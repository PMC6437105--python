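import pytest

from phagechar import PHAGE_PRESETS, NoiseModel


@pytest.fixture
def escherichia():
    return PHAGE_PRESETS["escherichia_myPSH2311"]


@pytest.fixture
def klebsiella():
    return PHAGE_PRESETS["klebsiella_myPSH1235"]


@pytest.fixture
def enterobacter():
    return PHAGE_PRESETS["enterobacter_myPSH1140"]


@pytest.fixture
def poisson_noise():
    return NoiseModel(count_noise=True, seed=42)
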