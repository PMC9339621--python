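import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from dstan import LabeledDataset, RoiTimeSeries, SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset():
    """8 subjects, 10 nodes, 30 timepoints, 3 planted nodes."""
    cfg = SyntheticConfig(n_nodes=10, n_timepoints=30,
                          n_subjects_per_class=4, planted_nodes=(0, 1, 2),
                          effect_delta=0.5, seed=3)
    return generate_dataset(cfg)


def random_dataset(rng, n_subjects=6, T=20, n=8) -> LabeledDataset:
    """Unstructured random subjects (no class signal), for plumbing
    tests."""
    subs = [RoiTimeSeries(rng.standard_normal((T, n)), f"sub-{i:03d}",
                          label=i % 2)
            for i in range(n_subjects)]
    return LabeledDataset(subs)
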