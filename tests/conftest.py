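import numpy as np
import pytest

import pupilforest as pf

SMALL_SCHEDULE = [
    pf.LayerConfig(n_forests=2, n_trees_per_forest=3, crop_scale=1.0),
    pf.LayerConfig(n_forests=3, n_trees_per_forest=4, crop_scale=0.5),
]


@pytest.fixture(scope="session")
def small_dataset():
    """60 rendered training scenes with exact annotations."""
    images, annotations, params = pf.generate_dataset(60, seed=1)
    return images, annotations, params


@pytest.fixture(scope="session")
def small_model(small_dataset):
    """A light 2-layer cascade used across the rule/tracking tests."""
    images, annotations, _ = small_dataset
    return pf.train_cascade(images, annotations, schedule=SMALL_SCHEDULE, seed=5)


@pytest.fixture(scope="session")
def held_out():
    """20 held-out scenes for quick prediction checks."""
    images, annotations, params = pf.generate_dataset(20, seed=99)
    return images, annotations, params


def make_samples(X, Y):
    return [pf.EyeSample(features=x, target=y) for x, y in zip(X, Y)]


@pytest.fixture
def step_samples():
    """1-D step data: two samples at target (0,0), two at (1,1)."""
    X = np.array([[0.1], [0.2], [0.8], [0.9]])
    Y = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
    return make_samples(X, Y)
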