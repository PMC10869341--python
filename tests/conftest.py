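import numpy as np
import pandas as pd
import pytest

from marshpace import LevelSeries, SyntheticConfig, generate_network


def monthly_series(values, start="2009-01", site_id="S1"):
    """Monthly LevelSeries helper with full completeness."""
    values = np.asarray(values, dtype=float)
    idx = pd.date_range(pd.Timestamp(start), periods=len(values), freq="MS")
    return LevelSeries(
        site_id, "monthly", pd.Series(values, index=idx),
        pd.Series(np.ones(len(values)), index=idx),
    )


@pytest.fixture(scope="session")
def tiny_config():
    return SyntheticConfig(n_sites=6, seed=11)


@pytest.fixture(scope="session")
def tiny_network(tiny_config):
    return generate_network(tiny_config)
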