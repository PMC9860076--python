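import numpy as np
import pandas as pd
import pytest

import germlayertracker as g


@pytest.fixture(scope="session")
def default_panel():
    return g.load_default_signatures()


@pytest.fixture(scope="session")
def labeled_dataset():
    """Small class-structured beta matrix with planted markers and truth."""
    config = g.SimulationConfig(seed=7, n_probes=300)
    return g.simulate_class_matrix(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_matrix(values, probes=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:08d}" for i in range(values.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(values.shape[1])]
    m = pd.DataFrame(values, index=probes, columns=samples)
    m.index.name = "probe_id"
    return m
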