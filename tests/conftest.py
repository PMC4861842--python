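import numpy as np
import pandas as pd
import pytest

from herdsense import features, synthgen
from herdsense.config import GeneratorConfig


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def barn(default_config):
    """One full default barn (16 cows x 22 days), shared by read-only tests."""
    return synthgen.generate(default_config, n_days=22, seed=123)


@pytest.fixture(scope="session")
def daily(barn):
    return features.daily_summaries(barn.visits, barn.rum_events,
                                    barn.milk, barn.cohort)


@pytest.fixture(scope="session")
def contaminated_barn():
    cfg = GeneratorConfig().contaminated(0.01)
    return synthgen.generate(cfg, n_days=22, seed=77)


def make_visits(rows) -> pd.DataFrame:
    """Small visits frame from (cow_id, duration_s, fmi_kg) tuples."""
    df = pd.DataFrame(rows, columns=["cow_id", "duration_s", "fmi_kg"])
    df.insert(1, "station_id", 1)
    df.insert(2, "day", 1)
    df.insert(3, "start_s", np.arange(len(df), dtype=float) * 1000.0)
    df["artifact"] = "none"
    df["replaced_field"] = "none"
    return df
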