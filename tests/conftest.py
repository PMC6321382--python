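import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pupsite.peptide_io import FeatureMatrix
from pupsite.synthetic import MotifSpec, generate_motif_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# resampling/eval modules log expected degenerate-case warnings on tiny
# fixtures; keep test output readable
logging.getLogger("pupsite").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def strong_dataset():
    """Separable 40:80 site dataset with a strong 3-position motif."""
    return generate_motif_dataset(
        40, MotifSpec.strong(imbalance=2.0, seed=3)
    )


@pytest.fixture(scope="session")
def null_small_dataset():
    """30:30 dataset with no class signal."""
    return generate_motif_dataset(30, MotifSpec.null(imbalance=1.0, seed=4))


def make_fm(values, prefix="s", names=None) -> FeatureMatrix:
    values = np.asarray(values, dtype=float)
    if names is None:
        names = [f"f{j}" for j in range(values.shape[1])]
    return FeatureMatrix(
        [f"{prefix}{i}" for i in range(values.shape[0])], list(names), values
    )


@pytest.fixture
def feature_matrix_factory():
    return make_fm
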