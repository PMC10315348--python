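import numpy as np
import pytest

from ringrelease.accounting import daily_protocol, monophasic_protocol, biphasic_protocol
from ringrelease.assessment import MediumSpec
from ringrelease.reference import DAPIVIRINE, IPA_WATER_SOLUBILITY


@pytest.fixture(scope="session")
def drug():
    return DAPIVIRINE


@pytest.fixture(scope="session")
def protocol_daily():
    """Simple 28-day daily full-replacement schedule, 100 mL."""
    return daily_protocol(28, volume=100.0)


@pytest.fixture(scope="session")
def protocol_weekend():
    """28-day schedule with weekend bridging (200 mL Friday refills)."""
    return monophasic_protocol(28)


@pytest.fixture(scope="session")
def protocol_biphasic():
    return biphasic_protocol(28)


@pytest.fixture(scope="session")
def medium_5050():
    return MediumSpec(label="50/50", solubility=IPA_WATER_SOLUBILITY["50/50"],
                      volume=100.0, cosolvent_percent=50.0)


@pytest.fixture(scope="session")
def medium_water():
    return MediumSpec(label="0/100", solubility=IPA_WATER_SOLUBILITY["0/100"],
                      volume=100.0, cosolvent_percent=0.0)
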