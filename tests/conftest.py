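import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_table(groups, tissue="liver", mediator="IL-6"):
    """Long-format table from {condition: values} (or {(tissue, mediator, condition): values})."""
    rows = []
    for key, values in groups.items():
        if isinstance(key, tuple):
            t, m, cond = key
        else:
            t, m, cond = tissue, mediator, key
        for i, v in enumerate(values):
            rows.append((f"{cond}_{i}", cond, t, m, float(v), 0.0))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "condition", "tissue", "mediator",
                 "concentration", "timepoint"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240215)
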