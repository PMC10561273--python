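import numpy as np
import pytest

from itdisp import moments, synthetic_data


@pytest.fixture(scope="session")
def paper_model():
    from itdisp.correlations import PAPER_MODEL

    return PAPER_MODEL


@pytest.fixture
def default_config():
    return synthetic_data.ExperimentConfig()


def centered_truth(true_Deff=2.5, **kw):
    """Truth with the release centered in the domain: boundaries stay out of
    reach over a 10-min window, so moment slopes reflect the free-space law."""
    kw.setdefault("true_Ufsi", 5.0)
    kw.setdefault("caudal_offset", 24.0)
    kw.setdefault("noise_sd", 0.0)
    kw.setdefault("lighting_gradient", 0.0)
    return synthetic_data.SyntheticTruth(true_Deff=true_Deff, **kw)


@pytest.fixture
def phase2_series(default_config):
    """Noiseless ground-truth profiles at 1-min snapshots, 1–10 min."""
    truth = centered_truth()
    return synthetic_data.simulate_truth(
        default_config, truth, np.arange(1.0, 11.0))


def gaussian_profile(x, center, sd, amplitude=1.0):
    return amplitude * np.exp(-((x - center) ** 2) / (2.0 * sd**2))


def fit_dexp(series, window=(1.0, 10.0)):
    return moments.estimate_dispersion(
        moments.compute_moments(series), window).Dexp
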