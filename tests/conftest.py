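import numpy as np
import pytest

from flyaging import spectra as sp
from flyaging.simulate import default_spectra_spec, simulate_spectra

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def default_spectrum_set():
    """One simulated run of the full default design (shared, read-only)."""
    return simulate_spectra(default_spectra_spec(), FIXTURE_SEED)


def _preprocessed(sset, tissue):
    sub = sset.select((sset.sample_meta["tissue"] == tissue).to_numpy())
    return sp.preprocess(sub)


@pytest.fixture(scope="session")
def head_processed(default_spectrum_set):
    return _preprocessed(default_spectrum_set, "head")


@pytest.fixture(scope="session")
def body_processed(default_spectrum_set):
    return _preprocessed(default_spectrum_set, "body")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
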