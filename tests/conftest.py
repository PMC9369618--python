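import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dsscreen import (
    ClassFrame,
    FeatureMatrix,
    SyntheticConfig,
    make_gaussian_dataset,
    make_toy_smiles_set,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def frame7() -> ClassFrame:
    return ClassFrame()


@pytest.fixture(scope="session")
def frame3() -> ClassFrame:
    return ClassFrame(("analgesic", "antineoplastic", "antibacterial"))


@pytest.fixture(scope="session")
def toy_records():
    return make_toy_smiles_set(4)


@pytest.fixture(scope="session")
def small_gaussian():
    """Well-separated 7-class data, uneven sizes, small enough for fast fits."""
    cfg = SyntheticConfig(seed=11, separation=6.0).scaled(0.1)
    fm, labels = make_gaussian_dataset(cfg)
    return fm, labels, cfg


@pytest.fixture()
def points_1d() -> FeatureMatrix:
    """The hand-checkable 1-D Kennard-Stone example {0, 1, 2, 10}."""
    return FeatureMatrix(
        pd.DataFrame({"x": [0.0, 1.0, 2.0, 10.0]}, index=["p0", "p1", "p2", "p10"]),
        "F2_descriptors",
    )


def random_mass(rng: np.random.Generator, c: int) -> np.ndarray:
    v = rng.dirichlet(np.ones(c))
    return v / v.sum()
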