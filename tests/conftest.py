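import numpy as np
import pytest

from walkassr.preprocess import PowerSpectrum
from walkassr.synth import SessionConfig


@pytest.fixture
def quiet_config():
    """Walking session with the stochastic sources silenced: pure sinusoidal
    ASSR sources on a negligible background, for analytic power checks."""
    return SessionConfig(
        movement_state="walk", n_laps=4, seed=11,
        alpha_amp={"stand": 0.0, "step": 0.0, "walk": 0.0},
        aperiodic=(-12.0, 1.0), noise_uv=0.0,
        erp_p1_uv=0.0, erp_p2_uv=0.0,
    )


@pytest.fixture
def short_walk_config():
    return SessionConfig(movement_state="walk", n_laps=8, seed=21)


def make_spectrum(freqs, log10_power):
    """PowerSpectrum from log10 power values."""
    return PowerSpectrum(freqs=np.asarray(freqs, float),
                         power=10.0 ** np.asarray(log10_power, float))


@pytest.fixture
def power_law_spectrum():
    def _make(offset=0.0, exponent=2.0, peaks=(), noise_sd=0.0, seed=0,
              freqs=None):
        f = np.arange(1.0, 48.5, 1.0) if freqs is None else np.asarray(freqs)
        logp = offset - exponent * np.log10(f)
        for c, h, sd in peaks:
            logp = logp + h * np.exp(-0.5 * ((f - c) / sd) ** 2)
        if noise_sd:
            logp = logp + np.random.default_rng(seed).normal(0, noise_sd, f.size)
        return make_spectrum(f, logp)
    return _make
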