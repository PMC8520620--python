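import pytest

from ccxover import CaseCrossoverDataset, CaseSeries
from ccxover.simulate import scenario_dataset


@pytest.fixture
def toy3() -> CaseCrossoverDataset:
    """Three cases, M=2: A exposed at case with controls (0,1); B unexposed
    with controls (1,0); C exposed with controls (0,0)."""
    return CaseCrossoverDataset(
        [
            CaseSeries("A", (1, 0, 1)),
            CaseSeries("B", (0, 1, 0)),
            CaseSeries("C", (1, 0, 0)),
        ]
    )


@pytest.fixture(scope="session")
def cyclic_21() -> CaseCrossoverDataset:
    """140 expected cases of the default cyclic population, M=21 daily periods."""
    return scenario_dataset("cyclic", 21)


@pytest.fixture(scope="session")
def motivating() -> CaseCrossoverDataset:
    """The 2-on/1-off cyclic example: patterns (1101), (1011), (0110) with
    case multiplicities 40, 40, 10."""
    return scenario_dataset("motivating")
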