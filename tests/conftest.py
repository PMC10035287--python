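import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def coupled_dataset():
    """Two-class trials with one strongly class-coupled channel pair.

    Channels 1 and 4 share a 16-30 Hz source with wavelet correlation ~0.9
    in class 0 and 0 in class 1 (level 5 at fs=1000), 40 trials per class.
    """
    from wavedisc.synthetic import CoupledPair, generate_dataset, small_scale_config

    cfg = small_scale_config(
        n_trials_per_class=40,
        coupled_pairs=(CoupledPair(1, 4, 16.0, 30.0, 0.9, 0.0),),
        seed=0,
    )
    trials, labels, truth = generate_dataset(cfg)
    return cfg, trials, labels, truth
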