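from datetime import timedelta, timezone

import pandas as pd
import pytest
from hypothesis import settings

from heatdex import GeneratorConfig, default_schemes, generate_series

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")

TZ2 = timezone(timedelta(hours=2))


@pytest.fixture(scope="session")
def schemes():
    return default_schemes()


@pytest.fixture(scope="session")
def study_series():
    """Synthetic series at the study-calibrated defaults (fixed seed)."""
    return generate_series(GeneratorConfig(seed=20231126))


@pytest.fixture()
def short_config():
    """A one-week generator config for fast tests."""
    return GeneratorConfig(
        start=pd.Timestamp("2023-12-01T00:00+02:00"),
        end=pd.Timestamp("2023-12-08T00:00+02:00"),
        seed=7,
    )
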