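import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

logging.getLogger("fprt").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20140829)


@pytest.fixture
def crossing_table_factory():
    """Build a long-format crossing table from a subjects x pairs value matrix."""

    def make(values, pair_names=None, status=None):
        values = np.asarray(values, dtype=float)
        s, k = values.shape
        pairs = pair_names or [f"P{j + 1}" for j in range(k)]
        rows = []
        for i in range(s):
            for j in range(k):
                rows.append({
                    "subject": f"s{i + 1:03d}",
                    "pair": pairs[j],
                    "cond_a": pairs[j].split(" vs ")[0],
                    "cond_b": pairs[j].split(" vs ")[-1],
                    "crossing": values[i, j],
                    "slope": -1.0,
                    "status": status or "ok",
                })
        return pd.DataFrame(rows)

    return make
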