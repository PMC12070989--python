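import numpy as np
import pytest

from lesiongraph.features import FEATURE_NAMES, FeatureTable, RegionFeatureVector
from lesiongraph.synth import ClassProfile


def make_row(region_id: int, values) -> RegionFeatureVector:
    """Build a RegionFeatureVector from a 14-vector (tests only)."""
    return RegionFeatureVector(region_id=region_id, **dict(zip(FEATURE_NAMES, map(float, values))))


def make_table(features, class_label="toy") -> FeatureTable:
    features = np.asarray(features, dtype=float)
    rows = [make_row(i + 1, f) for i, f in enumerate(features)]
    return FeatureTable(class_label=class_label, rows=rows)


def random_table(rng, n_rows, class_label="toy") -> FeatureTable:
    """Random but invariant-respecting feature table."""
    X = np.zeros((n_rows, 14))
    X[:, 0] = rng.uniform(10, 500, n_rows)  # area
    X[:, 1] = rng.uniform(5, 120, n_rows)  # perimeter
    X[:, 2] = rng.uniform(0, 0.99, n_rows)  # eccentricity
    X[:, 3] = rng.uniform(0.5, 1.0, n_rows)  # solidity
    X[:, 5] = rng.uniform(2, 15, n_rows)  # minor
    X[:, 4] = X[:, 5] * rng.uniform(1, 3, n_rows)  # major
    X[:, 6] = X[:, 4] / X[:, 5]  # aspect
    X[:, 8] = rng.uniform(0.3, 1.0, n_rows)  # circularity
    X[:, 7] = 1.0 / X[:, 8]  # compactness
    X[:, 9] = rng.uniform(0, 50, n_rows)  # contrast
    X[:, 10] = rng.uniform(-1, 1, n_rows)  # correlation
    X[:, 11] = rng.uniform(0.01, 1, n_rows)  # energy
    X[:, 12] = rng.uniform(0.1, 1, n_rows)  # homogeneity
    X[:, 13] = rng.uniform(0, 1, n_rows)  # mean intensity
    return make_table(X, class_label)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_profile():
    return ClassProfile(
        class_name="toy",
        area_range=(40, 120),
        n_regions_range=(1, 2),
        contrast_level=0.5,
        circularity_target=0.9,
        intensity_mean=0.6,
        canvas=(64, 64),
    )


#: strongly separated profiles for classifier recovery tests
def separated_profiles(canvas=(96, 96)):
    return (
        ClassProfile("classA", (60, 100), (1, 2), 0.05, 0.95, 0.75, canvas),
        ClassProfile("classB", (400, 600), (4, 6), 0.95, 0.45, 0.35, canvas),
    )
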