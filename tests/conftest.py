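import numpy as np
import pytest

from ftirquant import Spectrum, default_design, synth_spectrum


@pytest.fixture
def gaussian_spectrum():
    """Single Gaussian band (amplitude 0.5, sigma 5, center 1700) on 1600-1800."""
    wn = np.arange(1600.0, 1800.0 + 1, 1.0)
    a = 0.5 * np.exp(-0.5 * ((wn - 1700.0) / 5.0) ** 2)
    return Spectrum(wn, a, mode="absorbance")


@pytest.fixture
def mixture_spectrum():
    """Noiseless 0.5%/0.5% two-analyte mixture on the default grid."""
    return synth_spectrum(default_design(noise_sd=0.0, baseline=(0.0, 0.0)))
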