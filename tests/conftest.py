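import pytest
from hypothesis import HealthCheck, settings

from groeldesign import alla_like_fixture, hcha_like_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Kyte-Doolittle values retyped from the original publication, used by test
# oracles so they stay independent of the package's shipped scale asset.
KD_ORACLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


@pytest.fixture(scope="session")
def alla_record():
    return alla_like_fixture()


@pytest.fixture(scope="session")
def hcha_record():
    return hcha_like_fixture()
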