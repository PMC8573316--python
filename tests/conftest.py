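import numpy as np
import pandas as pd
import pytest

from envim.tables import AbundanceTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_table(values, modality="DNA", unit="RAW", prefix=("s", "f")):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    df = pd.DataFrame(
        values,
        index=[f"{prefix[0]}{i}" for i in range(n)],
        columns=[f"{prefix[1]}{j}" for j in range(p)],
    )
    return AbundanceTable(data=df, unit=unit, modality=modality)


@pytest.fixture
def raw_gene_table(rng):
    return make_table(rng.uniform(1, 10, size=(10, 20)))
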