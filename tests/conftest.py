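import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240426)


@pytest.fixture(scope="session")
def recovery_fit():
    """One shared full-observation fit of well-separated truth (n=300, d=4)."""
    import sitfpca as sf

    truth = sf.simple_curve_truth(B=15)
    data = sf.simulate_curves(truth, 300, 4, seed=1)
    model = sf.fit_mfpca(data.curves, data.mask, data.subjects, data.days, smooth="on")
    return truth, data, model
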