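import numpy as np
import pytest

from hhtmass.spectra_io import Spectrum


@pytest.fixture
def index_spectrum():
    """Factory: spectrum on a 1..n index-like axis with given intensities."""

    def make(intensity):
        intensity = np.asarray(intensity, dtype=float)
        return Spectrum(np.arange(intensity.size) + 1.0, intensity)

    return make


@pytest.fixture
def gaussian_spectrum(index_spectrum):
    """Factory: one or more Gaussians on a flat zero floor."""

    def make(n, centers, heights, sigmas, noise=0.0, seed=0):
        x = np.arange(n, dtype=float)
        y = np.zeros(n)
        for c, h, s in zip(centers, heights, sigmas):
            y += h * np.exp(-0.5 * ((x - c) / s) ** 2)
        if noise:
            y = y + np.random.default_rng(seed).normal(0.0, noise, size=n)
        return index_spectrum(y)

    return make
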