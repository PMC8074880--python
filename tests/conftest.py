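import numpy as np
import pytest

import squamorph as sq


@pytest.fixture(scope="session")
def stage_table():
    return sq.default_stage_table()


@pytest.fixture(scope="session")
def template():
    return sq.load_template_jaw()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def random_shape(rng, k=33, spread=1.0):
    """A non-degenerate random landmark configuration."""
    return rng.normal(0.0, spread, size=(k, 2))


def similarity_transform(rng, pts, scale_range=(0.2, 5.0), shift=10.0):
    """Apply a random rotation + positive scaling + translation."""
    theta = rng.uniform(-np.pi, np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    s = rng.uniform(*scale_range)
    t = rng.uniform(-shift, shift, size=2)
    return pts @ rot.T * s + t
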