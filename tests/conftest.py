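import numpy as np
import pytest

from polbkin import RateParameters, AssayConditions, AmplitudeModel
from polbkin.presets import FIGURE_CONDITIONS


@pytest.fixture
def wt_control() -> RateParameters:
    return FIGURE_CONDITIONS["wt_control"]


@pytest.fixture
def saturating_conditions() -> AssayConditions:
    return AssayConditions(enzyme_total=0.4, dna_total=0.2, dntp_0=500.0)


@pytest.fixture
def amp() -> AmplitudeModel:
    return AmplitudeModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_rate_parameters(rng: np.random.Generator, reversible: bool = True) -> RateParameters:
    """Random but physically plausible rate set spanning orders of magnitude."""

    def r(lo, hi):
        return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))

    return RateParameters(
        KD_dNTP=r(1, 100),
        kon_dNTP=r(10, 1000),
        k2f=r(1, 500),
        k2r=r(0.1, 50) if reversible else 0.0,
        k3f=r(0.5, 500),
        k3r=r(0.1, 50) if reversible else 0.0,
        k4f=r(0.5, 50),
        k4r=0.0,
        k5f=r(0.5, 100),
        k5r=0.0,
    )
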