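import numpy as np
import pytest

from emgstyle.canonical import FeatureMatrix, standardize_columns
from emgstyle.experiment import UserDataset
from emgstyle.synthgen import generate_multiuser_features


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_standardized_pair(rows, p, q, c, seed):
    """Two class-matched, column-standardized random views (shared labels)."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(1, c + 1), rows // c)
    X = FeatureMatrix(rng.standard_normal((labels.size, p)), labels)
    Y = FeatureMatrix(rng.standard_normal((labels.size, q)), labels)
    Xs, _ = standardize_columns(X)
    Ys, _ = standardize_columns(Y)
    return Xs, Ys


@pytest.fixture(scope="session")
def small_users():
    """A compact multi-user set for experiment-level tests (fast)."""
    users = generate_multiuser_features(
        n_users=4, c=5, n_per_class=14, feature_dim=24, latent_dim=4,
        style_strength=1.0, seed=7,
    )
    return {
        uid: UserDataset.from_feature_matrix(fm, calibration_per_class=6, seed=7)
        for uid, fm in users.items()
    }


@pytest.fixture(scope="session")
def default_users():
    """The default study-scale generator output (8 users, 12 classes, 64 dims)."""
    users = generate_multiuser_features(seed=0)
    return {
        uid: UserDataset.from_feature_matrix(fm, calibration_per_class=8, seed=0)
        for uid, fm in users.items()
    }
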