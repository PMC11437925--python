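import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def separable_task():
    """Well-separated 3-class blobs: Bayes accuracy ~ 1."""
    from banditdose import make_classification_task

    return make_classification_task(600, d=4, K=3, class_separation=6.0, seed=11)


@pytest.fixture(scope="session")
def noisy_task():
    """Overlapping 3-class blobs: genuinely uncertain imputation."""
    from banditdose import make_classification_task

    return make_classification_task(500, d=4, K=3, class_separation=1.2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def stub_ensemble(prop_matrices):
    """Build a PropensityEnsemble whose members return fixed probability
    matrices, for hand-arithmetic fixtures."""
    from banditdose import PropensityEnsemble

    class _Stub:
        def __init__(self, P):
            self.P = np.asarray(P, float)
            self.n_out = self.P.shape[1]

        def predict_proba(self, X):
            return self.P[: np.atleast_2d(X).shape[0]]

    return PropensityEnsemble(
        members=[_Stub(P) for P in prop_matrices], kind="nn-ensemble"
    )


@pytest.fixture()
def make_stub_ensemble():
    return stub_ensemble
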