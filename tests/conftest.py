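import numpy as np
import pytest

from cascadefis import synthgen


@pytest.fixture(scope="session")
def small_dataset():
    """3 classes x 12 pose-swept frames, maximally hue-separable."""
    return synthgen.generate(3, 12, seed=11, separability=1.0)


@pytest.fixture(scope="session")
def sample_image(small_dataset):
    return small_dataset.images[0]


def make_separable_groups(n_classes=3, n_per=40, n_groups=3, dim=9, seed=1):
    """Tabular grouped features with well-separated class centroids."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 5, (n_classes, n_groups, dim))
    labels = [f"cls{c}" for c in range(n_classes) for _ in range(n_per)]
    tables = [
        np.vstack([
            centers[c, g] + rng.normal(0, 0.3, (n_per, dim))
            for c in range(n_classes)
        ])
        for g in range(n_groups)
    ]
    return tables, labels


@pytest.fixture(scope="session")
def separable_groups():
    return make_separable_groups()
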