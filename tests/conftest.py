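import dataclasses

import numpy as np
import pytest

from paddywave.spectra_io import CANONICAL_GRID, Spectrum
from paddywave.synthetic_data import SynthConfig, simulate_trial


@pytest.fixture(scope="session")
def noiseless_cfg() -> SynthConfig:
    return dataclasses.replace(SynthConfig(), sensor_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_trial(noiseless_cfg):
    """One noiseless default trial shared across tests (seed 7)."""
    return simulate_trial(noiseless_cfg, 7)


@pytest.fixture
def smooth_spectrum() -> Spectrum:
    """An analytic, infinitely smooth canopy-like test curve."""
    lam = CANONICAL_GRID
    r = 0.3 + 0.15 * np.sin(2 * np.pi * lam / 400.0) + 0.05 * np.exp(-0.5 * ((lam - 700) / 60.0) ** 2)
    return Spectrum("smooth", "heading", lam, r)
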