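import numpy as np
import pytest

from hyperclass.data_model import ACTIONS, SampleSet
from hyperclass.synth import SyntheticConfig, generate_pair, pair_samples


@pytest.fixture(scope="session")
def small_pair():
    """A cheap misaligned pair with strong signal for pipeline-level tests."""
    cfg = SyntheticConfig(n_voxels=120, n_signal_voxels=48, effect_size=0.3,
                          seed=7)
    return generate_pair(cfg)


@pytest.fixture(scope="session")
def small_samples(small_pair):
    return pair_samples(small_pair)


@pytest.fixture(scope="session")
def default_pair():
    """The benchmark pair at full default study conditions."""
    return generate_pair(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_samples(default_pair):
    return pair_samples(default_pair)


def make_sampleset(x, labels=None, runs=None, rng_seed=0):
    """Quick SampleSet around a matrix, cycling labels if not given."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if labels is None:
        labels = np.array([ACTIONS[i % 4] for i in range(n)], dtype=object)
    if runs is None:
        runs = np.zeros(n, dtype=int)
    return SampleSet(x, np.asarray(labels, dtype=object), runs, np.arange(n))
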