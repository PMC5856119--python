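import numpy as np
import pytest

from hsbrain import (ClassifierConfig, PhantomSpec, PreprocessConfig,
                     generate_dataset, train_classifier)
from hsbrain.hsio import HyperCube


@pytest.fixture
def tiny_cube():
    """A deterministic 4x5x6 raw cube with a 400-1000 nm axis."""
    rng = np.random.default_rng(42)
    data = rng.uniform(10, 200, size=(4, 5, 6))
    wl = np.linspace(400, 1000, 6)
    return HyperCube(data, wl, units="raw", name="tiny")


@pytest.fixture(scope="session")
def fast_spec():
    """Desk-scale phantom conditions used by the quicker end-to-end tests."""
    return PhantomSpec(rows=40, cols=40, bands=60, background_ring_px=6,
                       tumor_radius=0.16)


@pytest.fixture(scope="session")
def fast_preprocess():
    return PreprocessConfig(target_bands=32)


@pytest.fixture(scope="session")
def fast_campaign(fast_spec, fast_preprocess):
    """A small multi-subject phantom campaign: dataset, holdout scene, model."""
    ds, holdouts = generate_dataset(fast_spec, n_subjects=3, seed=7,
                                    max_per_class=150,
                                    preprocess_config=fast_preprocess)
    model = train_classifier(ds, ClassifierConfig(seed=7))
    return ds, holdouts[0], model
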