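import numpy as np
import pytest

from cadenza import synth, tiecks


@pytest.fixture(scope="session")
def param_table():
    return tiecks.load_parameter_table()


@pytest.fixture(scope="session")
def templates_task():
    """ARI templates on the 256-sample / 5 Hz task-segment grid."""
    return tiecks.make_templates(5.0, 51.2)


@pytest.fixture(scope="session")
def quiet_spec():
    """Stationary, noise-free generator spec (no task modulation)."""
    return synth.SyntheticSpec(
        seed=0,
        noise_sd_pct=0.0,
        nvc_amplitude_pct=0.0,
        map_rise_mmHg=0.0,
        hr_rise_bpm=0.0,
        etco2_drift_mmHg=0.0,
        true_ari_task=6,
    )


def band_limited_noise(rng: np.random.Generator, n: int, rate: float = 5.0,
                       band=(0.02, 0.45), slope: float = -0.5) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to ``band`` (test helper)."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.zeros(len(freqs), dtype=complex)
    spec[sel] = freqs[sel] ** slope * np.exp(1j * rng.uniform(0, 2 * np.pi, sel.sum()))
    x = np.fft.irfft(spec, n)
    return x / x.std()
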