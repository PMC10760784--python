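import logging

import numpy as np
import pandas as pd
import pytest

from primir import ExpressionMatrix, SynthConfig, generate_world

# solver/CV warnings are expected in stress tests; keep output readable
logging.getLogger("primir").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by read-only tests."""
    cfg = SynthConfig(n_samples=80, n_mrnas=60, n_primirnas=4,
                      support_size=5, n_groups=20, seed=11)
    return generate_world(cfg)


@pytest.fixture()
def toy_matrix():
    """A 4x4 expression matrix with easy hand-checkable structure."""
    rng = np.random.default_rng(5)
    data = pd.DataFrame(
        rng.uniform(0.5, 20.0, size=(4, 4)),
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(4)],
    )
    return ExpressionMatrix(data, transform="raw_tpm")
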