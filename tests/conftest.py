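import math

import pytest

from eggrisk import (
    ConcentrationSummary,
    default_analyte_params,
    default_exposure_params,
    fixture_small,
)


@pytest.fixture
def ep():
    """Default adult exposure bundle (25.4 g/day, 70 kg, lifetime averaging)."""
    return default_exposure_params()


@pytest.fixture
def analytes():
    """Default Pb/Cd toxicological and regulatory parameters."""
    return default_analyte_params()


@pytest.fixture
def pb_summary():
    """The published Pb concentration summary row (µg/kg, n=42)."""
    return ConcentrationSummary(
        analyte="Pb", n=42, mean=7.158, se=0.248, min=2.400, max=9.000,
        range=6.6, sd=0.248 * math.sqrt(42),
    )


@pytest.fixture
def cd_summary():
    """The published Cd concentration summary row (µg/kg, n=42)."""
    return ConcentrationSummary(
        analyte="Cd", n=42, mean=2.83, se=0.151, min=1.190, max=5.000,
        range=3.81, sd=0.151 * math.sqrt(42),
    )


@pytest.fixture
def small_table():
    """Fixed 6-egg two-analyte table with exactly known statistics."""
    return fixture_small()
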