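import numpy as np
import pytest

from synaptiq import (
    AcquisitionSpec,
    BoutonPopulation,
    ColocConfig,
    VolumeSpec,
    generate_volume,
)


@pytest.fixture(scope="session")
def default_config():
    return ColocConfig()


@pytest.fixture(scope="session")
def clean_volume():
    """Small noiseless volume with perfectly co-localizing markers."""
    spec = VolumeSpec(shape_xy=(256, 256), seed=42, background_sd=0.0)
    # separation beyond the punctum render extent so no tail of one bouton
    # reaches another bouton's VOI
    pop = BoutonPopulation(count=24, noise_sd=0.0, epsilon_sd=0.0, alpha=1.0,
                           peak_sd=0.0, min_separation_um=3.0)
    return generate_volume(spec, pop)


@pytest.fixture(scope="session")
def noisy_volume():
    """Realistic volume: 8-bit noise, high peak/background contrast."""
    spec = VolumeSpec(shape_xy=(256, 256), seed=7, background_mean=20,
                      background_sd=4.0)
    pop = BoutonPopulation(count=40, noise_sd=4.0, p_glyt2=0.4)
    return generate_volume(spec, pop)


@pytest.fixture
def single_stim_acq():
    return AcquisitionSpec(sweep_duration=0.3, stimulus_times=(0.1,))


def kernel_trace(acq, kernel, onsets_s, amplitudes=None):
    """Noise-free trace with unit-peak ``kernel`` placed at given onsets."""
    trace = np.zeros(acq.n_samples)
    if amplitudes is None:
        amplitudes = np.ones(len(onsets_s))
    for t0, a in zip(onsets_s, amplitudes):
        i = int(round(t0 * acq.sampling_rate))
        n = min(len(kernel), acq.n_samples - i)
        trace[i : i + n] += a * kernel[:n]
    return trace
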