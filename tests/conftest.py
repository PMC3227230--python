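import numpy as np
import pytest

from cardioshape import (
    LandmarkShape,
    align_shapes,
    build_model,
    make_training_set,
)
from cardioshape.synthetic import PhantomSpec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tetra_shape():
    """Minimal non-degenerate 4-landmark shape."""
    return LandmarkShape(np.array([
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
    ]))


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def small_training(phantom_spec):
    """40 synthetic endocardial grids with known planted modes."""
    return make_training_set(phantom_spec, 40, seed=7)


@pytest.fixture(scope="session")
def small_model(small_training):
    alignment = align_shapes(small_training.shapes)
    return build_model(alignment, 6)


@pytest.fixture(scope="session")
def small_alignment(small_training):
    return align_shapes(small_training.shapes)
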