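import numpy as np
import pytest
from hypothesis import settings

import biofiltervoc as bv

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def mm_profile():
    """Michaelis-Menten methanol profile at phi = beta = 10 on 1001 nodes."""
    return bv.solve_biofilm_bvp(bv.DimensionlessBiofilmParams(phi=10.0, beta=10.0))


@pytest.fixture(scope="session")
def surrogate_runs(mm_profile):
    """Ten independent surrogate trainings on the phi = beta = 10 profile.

    Returns a list of (seed, dataset, weights, record, report) tuples;
    shared by the training-quality and optimizer-correctness tests so the
    expensive runs happen once.
    """
    out = []
    for seed in range(10):
        dataset = bv.build_dataset(mm_profile, seed=seed)
        config = bv.ENNConfig(seed=seed)
        weights, record = bv.train(config, dataset)
        y = bv.predict(weights, dataset.x_points)
        te = dataset.test_idx
        report = bv.evaluate(y[te], dataset.targets[te], label=f"seed-{seed}")
        out.append((seed, dataset, weights, record, report))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
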