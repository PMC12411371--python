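import numpy as np
import pandas as pd
import pytest

from reprofeat.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_study():
    """Miniature distributed-scenario study shared across tests."""
    cfg = GeneratorConfig(n_train=60, n_test=30, n_features=20,
                          scenario="distributed", seed=11)
    return cfg, generate(cfg)


def make_replicates(rng, n=200, n_features=5, reliability=0.7):
    """Plain two-replicate tables with a known reliability ratio."""
    rel = np.full(n_features, reliability, dtype=float)
    s = rng.standard_normal((n, n_features)) * np.sqrt(rel)
    e1 = rng.standard_normal((n, n_features)) * np.sqrt(1 - rel)
    e2 = rng.standard_normal((n, n_features)) * np.sqrt(1 - rel)
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    cols = [f"f{j}" for j in range(n_features)]
    return (pd.DataFrame(s + e1, index=idx, columns=cols),
            pd.DataFrame(s + e2, index=idx, columns=cols))
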