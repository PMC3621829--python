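"""Shared fixtures: a trained sharpness model and small virtual slides.

Everything is generated programmatically from fixed seeds; no data files.
Session scope keeps the expensive pieces (SVM training, slide scoring)
to one computation per run.
"""

import numpy as np
import pytest

import cytofocus as cf
from cytofocus.sharpness import train_model


@pytest.fixture(scope="session")
def sharpness_model():
    """RBF-SVM trained on a small balanced synthetic cell set."""
    return train_model(cf.make_training_set(60, seed=11), seed=11)


@pytest.fixture(scope="session")
def small_slide():
    """A 1 mm desk slide with 400 cells on a 20 µm focal range."""
    return cf.make_virtual_slide(width_um=1000.0, height_um=1000.0,
                                 n_cells=400, seed=5)


@pytest.fixture(scope="session")
def dusty_sparse_slide():
    """Few cells, heavy dust: probes frequently lock onto the dust plane."""
    return cf.make_virtual_slide(width_um=1000.0, height_um=1000.0,
                                 n_cells=60, dust_density_per_mm2=400.0,
                                 seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
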