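import numpy as np
import pytest
from hypothesis import settings

from duplexdyn import synthetic as syn
from duplexdyn.tcspc import fit_global

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def duplex_dataset():
    """Study-condition synthetic dataset: tri-exponential decays at 12
    emission wavelengths, Gaussian IRF, peak 1e4 counts."""
    spec = syn.duplex_decay_spec()
    return syn.gen_decay_dataset(spec, syn.IRFSpec(), seed=42)


@pytest.fixture(scope="session")
def duplex_spec():
    return syn.duplex_decay_spec()


@pytest.fixture(scope="session")
def duplex_fit(duplex_dataset):
    return fit_global(duplex_dataset, n_components=3)


@pytest.fixture(scope="session")
def duplex_truth(duplex_spec):
    """Ground-truth species amplitudes and average lifetime of the default
    duplex spec, from exact quadrature of the generator bands."""
    w = duplex_spec.amplitude_spectra * np.asarray(duplex_spec.lifetimes)[:, None]
    total = np.trapezoid(w.sum(axis=0), duplex_spec.wavelengths)
    A = np.trapezoid(w, duplex_spec.wavelengths, axis=1) / total
    tau_av = float(np.sum(A * duplex_spec.lifetimes) / A.sum())
    return {"A": A, "tau_av": tau_av, "lifetimes": np.asarray(duplex_spec.lifetimes)}
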