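import numpy as np
import pytest

import accubound as ab

# reference parameter sets used throughout the suite
LSA_DRIFT = (-0.29, 1.43)
LSA_NOISE = (1.78,)
NONLIN_DRIFT = (-0.03, 0.17, 0.0, 0.81)
NONLIN_NOISE = (0.01, -0.01, 1.72)
EMPIRICAL_TARGET = (5.95, 21.96)


@pytest.fixture(scope="session")
def lsa_model():
    return ab.LangevinModel(LSA_DRIFT, LSA_NOISE)


@pytest.fixture(scope="session")
def nonlinear_model():
    return ab.LangevinModel(NONLIN_DRIFT, NONLIN_NOISE)


@pytest.fixture(scope="session")
def ou_dataset():
    """60 trials x 750 samples of the LSA (OU) ground truth, model units."""
    cfg = ab.GroundTruthConfig(drift_coeffs=LSA_DRIFT, noise_coeffs=LSA_NOISE,
                               n_trials=60, n_channels=1,
                               amplitude_scale=1.0, seed=1234)
    return ab.generate_dataset(cfg)


@pytest.fixture(scope="session")
def long_ou_epoch():
    """One 10^5-sample OU series (g = -x, h = 1) in model units."""
    cfg = ab.GroundTruthConfig(drift_coeffs=(-1.0, 0.0), noise_coeffs=(1.0,),
                               n_trials=1, n_channels=1, amplitude_scale=1.0,
                               epoch_duration=400.0, event_latency=200.0,
                               seed=77)
    return ab.generate_dataset(cfg).select()[0]


def ig_se(mu, lam, n):
    """Asymptotic standard errors of the IG MLE (mu-hat, lam-hat)."""
    return np.sqrt(mu ** 3 / (lam * n)), lam * np.sqrt(2.0 / n)
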