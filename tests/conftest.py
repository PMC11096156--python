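import numpy as np
import pytest

from pearloct.features import assemble_features
from pearloct.grading import FeatureTable
from pearloct.preprocess import locate_roi
from pearloct.simulate import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig()


@pytest.fixture(scope="session")
def small_dataset(synth_cfg):
    """8 B-scans per grade — enough for stratified 5-fold CV after an 80/20 split."""
    return generate_dataset(synth_cfg, n_per_class=8, seed=2024)


def extract_table(dataset) -> FeatureTable:
    rows = []
    for img, _label in zip(dataset.images, dataset.labels):
        roi, _, _ = locate_roi(img)
        rows.append(assemble_features(roi).values)
    return FeatureTable(np.array(rows), np.array(dataset.labels))


@pytest.fixture(scope="session")
def small_table(small_dataset):
    """Feature table of the 32-image synthetic dataset (session cached)."""
    return extract_table(small_dataset)


@pytest.fixture(scope="session")
def speckle_roi(synth_cfg):
    """One realistic speckle ROI from the generator (grade C)."""
    from pearloct.simulate import generate_bscan

    img = generate_bscan(synth_cfg, "C", rng=np.random.default_rng(77))
    roi, _, _ = locate_roi(img)
    return roi
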