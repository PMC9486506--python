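import numpy as np
import pytest

import growthfeedback as gf


@pytest.fixture(scope="session")
def params():
    """Shipped calibrated dimensional model parameters."""
    return gf.default_model_params()


@pytest.fixture(scope="session")
def regulation():
    return gf.default_regulation_params()


@pytest.fixture(scope="session")
def wt_surface():
    """Wild-type regulation surface from the noiseless synthetic pipeline."""
    return gf.wildtype_surface()


@pytest.fixture(scope="session")
def sensitivity_chain(wt_surface, params):
    """Fitted Hill exponents of the calibrated model under the four scenarios."""
    return gf.dose_sensitivity_chain(surface=wt_surface, params=params)


def make_hill_curve(n, ic50, conc, g0=1.0, noise_sd=0.0, seed=0):
    """Dose-response data lying on (or scattered around) a known Hill curve."""
    rng = np.random.default_rng(seed)
    growth = g0 * gf.hill(conc, n, ic50)
    if noise_sd:
        growth = np.clip(growth + rng.normal(0, noise_sd, len(conc)), 1e-6, None)
    return gf.DoseResponseCurve(conc=conc, growth=growth)
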