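"""Shared fixtures: tiny hybrid problems that integrate in milliseconds."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import biohybrid as bh

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_species():
    return bh.SpeciesSet(("Xv", "A", "B"), np.array([10.0, 5.0, 2.0]))


@pytest.fixture
def feed_stream(small_species):
    return bh.FeedStream(np.array([0.0, 3.0, 0.0]), ((0.0, 6.0, 0.02),))


def _tiny_dataset(species, stream, seed=0, n_times=4, scale=30.0, hidden=(4,),
                  activation="tanh"):
    """Dataset measured on the trajectory of a random reference network, so a
    same-architecture model can in principle reach zero residuals."""
    rng = np.random.default_rng(seed)
    truth = bh.HybridModel.initialized(
        species, hidden, activation, seed=seed, volume_input=1.5, substep=0.5
    )
    truth = truth.with_weights(truth.weights.flatten() * scale)
    times = np.linspace(0.0, 6.0, n_times)
    c0 = np.array([3.0, 2.0, 1.0])
    state = bh.ProcessState(c0.copy(), 1.0, 0.0)
    traj = truth.simulate(state, [stream], times)
    sig = 0.1 * np.maximum(np.abs(traj.conc), 0.2)
    exp = bh.Experiment("e1", times, traj.conc.copy(), sig, c0, 1.0, (stream,))
    return bh.ExperimentDataset(species, [exp]), truth


@pytest.fixture
def tiny_problem(small_species, feed_stream):
    """(dataset, truth model): 3 species, 4 time points, 23-weight tanh net."""
    return _tiny_dataset(small_species, feed_stream)


@pytest.fixture
def tiny_dataset_factory(small_species, feed_stream):
    def make(**kw):
        return _tiny_dataset(small_species, feed_stream, **kw)

    return make
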