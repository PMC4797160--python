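import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wintercmr import CJSData, default_reach_table, simulate_dataset, simulate_histories

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def reach():
    return default_reach_table()


@pytest.fixture(scope="session")
def sim_dataset():
    """One full synthetic study bundle shared across read-only tests."""
    return simulate_dataset(seed=11)


def make_cjs_data(n=300, T=8, phi=0.85, p=0.5, seed=0, groups=None):
    """Simple homogeneous encounter data for likelihood-level tests."""
    rng = np.random.default_rng(seed)
    H = simulate_histories(np.full((n, T - 1), phi), np.full((n, T - 1), p), rng)
    g = np.array(groups if groups is not None else ["sculpin"] * n)
    return CJSData(histories=H, groups=g)
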