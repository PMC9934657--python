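import numpy as np
import pytest

from csakit.spectra import FragmentSpectrum


def make_random_spectrum(rng, n_peaks=None, mz_range=(60.0, 900.0), precursor=False):
    n = int(n_peaks if n_peaks is not None else rng.integers(2, 15))
    mz = np.sort(rng.uniform(*mz_range, size=n))
    while np.any(np.diff(mz) == 0):
        mz = np.sort(rng.uniform(*mz_range, size=n))
    intensity = rng.uniform(1.0, 1000.0, size=n)
    return FragmentSpectrum(
        mz, intensity,
        precursor_mz=float(mz.max() + rng.uniform(1, 50)) if precursor else None,
        metadata={"Name": f"random_{int(rng.integers(0, 10**9))}"},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_spectrum(rng):
    return make_random_spectrum(rng)


@pytest.fixture
def spectrum_factory(rng):
    def factory(**kwargs):
        return make_random_spectrum(rng, **kwargs)

    return factory
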