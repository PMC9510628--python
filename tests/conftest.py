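import numpy as np
import pytest

from fada.fourier import FourierSeries, reconstruct
from fada.simulate import SimulationSpec, generate_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def band_limited(rng, T=100, K=8, duration_s=1.0):
    """Random smooth real signal, exactly band-limited to K harmonics."""
    coeffs = np.zeros(K + 1, dtype=complex)
    coeffs[0] = rng.normal()
    coeffs[1:] = (rng.normal(size=K) + 1j * rng.normal(size=K)) / np.arange(1, K + 1)
    return reconstruct(FourierSeries(coeffs, duration_s), T), coeffs


@pytest.fixture
def small_bundle():
    """One small noiseless delayed-temporal ground-truth bundle."""
    spec = SimulationSpec(model_kind="temporal_delays", nonneg=False,
                          M=5, L=6, T=80, P=2, K_gen=6, seed=7,
                          n_realizations=1)
    return generate_benchmark(spec)[0]
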