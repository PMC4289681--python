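import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20141231)


def make_site_table(n_sites, chrom="1", spacing=1000):
    return pd.DataFrame({
        "chrom": chrom,
        "pos": 1 + spacing * np.arange(n_sites),
        "ref": "A",
        "alt": "C",
    })


@pytest.fixture
def site_table_factory():
    return make_site_table
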