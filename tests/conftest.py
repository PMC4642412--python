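import numpy as np
import pytest

from tailorpa.energy import BMREquationTable, IntensityThresholds, PositionCorrectionTable


@pytest.fixture(scope="session")
def position_table():
    return PositionCorrectionTable.default()


@pytest.fixture(scope="session")
def bmr_table():
    return BMREquationTable.default()


@pytest.fixture(scope="session")
def thresholds():
    return IntensityThresholds()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
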