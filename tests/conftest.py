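import numpy as np
import pytest

from epiforage.task import build_scene_model, random_scene
from epiforage.agent import run_trial


@pytest.fixture(scope="session")
def model():
    """Default single-trial model: c = 2, prior beta = 1, six epochs."""
    return build_scene_model(c=2.0, beta_prior=1.0, T=6)


@pytest.fixture(scope="session")
def tiny_model():
    """Two-epoch model for closed-form inference checks."""
    return build_scene_model(c=2.0, beta_prior=1.0, T=2)


@pytest.fixture(scope="session")
def batch_32(model):
    """32 seeded random trials under default conditions (shared across tests)."""
    trials = []
    for i in range(32):
        rng = np.random.default_rng([7, i])
        scene = random_scene(rng)
        trials.append(run_trial(model, scene, seed=int(rng.integers(2**31))))
    return trials


def random_expectations(rng, T, dims=(3, 8, 2, 2), n_policies=1):
    """Random normalized factor expectations, shape (P, T, dim) each."""
    out = []
    for d in dims:
        x = rng.random((n_policies, T, d))
        out.append(x / x.sum(axis=-1, keepdims=True))
    return out
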