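import os
import sys

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # make tests/_oracles.py importable

from glycophos.containers import IntensityMatrix, make_design
from glycophos.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def design():
    return make_design()


@pytest.fixture(scope="session")
def small_dataset():
    """Small seeded three-layer dataset shared by read-only tests."""
    cfg = SimulationConfig(n_global=150, n_glyco=200, n_phospho=300, seed=5)
    return generate_dataset(cfg)


def matrix_from(values, sample_ids=None, feature_ids=None, scale="log2",
                layer="global"):
    values = np.asarray(values, float)
    n_feat, n_samp = values.shape
    feature_ids = feature_ids or [f"f{i}" for i in range(n_feat)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samp)]
    df = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                      columns=sample_ids)
    return IntensityMatrix.from_values(df, scale=scale, layer=layer)
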