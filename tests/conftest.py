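import numpy as np
import pandas as pd
import pytest

from ecohealth import (
    Direction,
    IndicatorDefinition,
    IndicatorPanel,
    Subsystem,
    load_fixture_shandong,
)


@pytest.fixture(scope="session")
def shandong():
    return load_fixture_shandong()


@pytest.fixture
def small_definitions():
    """Two indicators per subsystem, one negative-direction column."""
    return (
        IndicatorDefinition("X_1", "econ a", Subsystem.ECONOMIC, Direction.POSITIVE),
        IndicatorDefinition("X_2", "econ b", Subsystem.ECONOMIC, Direction.POSITIVE),
        IndicatorDefinition("Y_1", "eco a", Subsystem.ECOLOGICAL, Direction.POSITIVE),
        IndicatorDefinition("Y_2", "eco b", Subsystem.ECOLOGICAL, Direction.NEGATIVE),
        IndicatorDefinition("Z_1", "hum a", Subsystem.HUMAN, Direction.POSITIVE),
        IndicatorDefinition("Z_2", "hum b", Subsystem.HUMAN, Direction.POSITIVE),
    )


@pytest.fixture
def small_panel(small_definitions):
    rng = np.random.default_rng(7)
    years = pd.Index(range(2010, 2016), name="year")
    values = pd.DataFrame(
        rng.uniform(1.0, 10.0, size=(len(years), len(small_definitions))),
        index=years,
        columns=[d.id for d in small_definitions],
    )
    return IndicatorPanel(values=values, definitions=small_definitions)


def random_panel(seed, n_years=5, per_subsystem=2, definitions=None):
    """Small random raw panel used by the oracle-equivalence suites."""
    rng = np.random.default_rng(seed)
    if definitions is None:
        definitions = []
        for sub, prefix in [
            (Subsystem.ECONOMIC, "X"),
            (Subsystem.ECOLOGICAL, "Y"),
            (Subsystem.HUMAN, "Z"),
        ]:
            for i in range(1, per_subsystem + 1):
                definitions.append(
                    IndicatorDefinition(f"{prefix}_{i}", "r", sub, Direction.POSITIVE)
                )
    years = pd.Index(range(2000, 2000 + n_years), name="year")
    values = pd.DataFrame(
        rng.uniform(0.5, 20.0, size=(n_years, len(definitions))),
        index=years,
        columns=[d.id for d in definitions],
    )
    return IndicatorPanel(values=values, definitions=tuple(definitions))
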