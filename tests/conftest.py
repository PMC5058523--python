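import numpy as np
import pytest

from snailrisk import (Grid, GridStack, LandscapeSpec, TruthModel,
                       gen_env_stack, sample_occurrences, true_suitability)

# The canonical strong-signal study condition used across recovery tests:
# two active predictors (one linear, one quadratic) and three inactive ones
# on a 100x100 autocorrelated landscape; presences concentrate tightly
# enough that a correct model separates them cleanly from background.
STRONG_TRUTH = {"env1": (4.0, 0.0), "env2": (0.0, -3.0)}
STRONG_INTERCEPT = -3.0
ACTIVE_VARS = ("env1", "env2")
INACTIVE_VARS = ("env3", "env4", "env5")


@pytest.fixture(scope="session")
def landscape100():
    spec = LandscapeSpec(nrows=100, ncols=100, n_vars=5,
                         smoothing_radius=3, seed=0)
    return gen_env_stack(spec)


@pytest.fixture(scope="session")
def strong_truth_surface(landscape100):
    truth = TruthModel(dict(STRONG_TRUTH), intercept=STRONG_INTERCEPT)
    return true_suitability(landscape100, truth)


@pytest.fixture(scope="session")
def strong_presences(strong_truth_surface):
    return sample_occurrences(strong_truth_surface, 500, seed=1)


@pytest.fixture
def grid4x4():
    vals = np.arange(16, dtype=float).reshape(4, 4)
    return Grid(values=vals, xmin=10.0, ymax=8.0, cell_size=0.5)


def make_grid(values, **kw):
    return Grid(values=np.asarray(values, dtype=float), **kw)


def make_binary_grid(rng, shape=(8, 8), p=0.5, **kw):
    return Grid(values=(rng.random(shape) < p).astype(float), **kw)
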