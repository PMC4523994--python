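import numpy as np
import pytest
from hypothesis import settings

import fdrboot as fb

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

SEED = 20150804


@pytest.fixture(scope="session")
def default_params():
    return fb.MixtureParams()


@pytest.fixture(scope="session")
def mixture_truth(default_params):
    """One fixed synthetic dataset from the default mixture (m=2000)."""
    return fb.simulate_pvalues(default_params, seed=SEED)


@pytest.fixture(scope="session")
def mixture_fit(mixture_truth):
    pv = mixture_truth.pvalue_vector()
    fit = fb.local_fdr(pv)
    S = fb.significant_set(fit, alpha=0.05)
    return pv, fit, S


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
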