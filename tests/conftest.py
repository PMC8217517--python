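import numpy as np
import pytest

from dbck import cosa, synthgen


@pytest.fixture(scope="session")
def default_params():
    return synthgen.SynthParams(n_specimens=40, seed=7)


@pytest.fixture(scope="session")
def small_population(default_params):
    return synthgen.make_population(default_params)


@pytest.fixture(scope="session")
def noise_free_params():
    return synthgen.SynthParams(n_specimens=12, seed=11,
                                landmark_noise_sd=0.0,
                                localization_noise_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_population(noise_free_params):
    return synthgen.make_population(noise_free_params)


@pytest.fixture()
def straight_specimen():
    """A noise-free, exactly straight specimen (ψ = 0, zero wave)."""
    params = synthgen.SynthParams(
        n_specimens=1, seed=3, landmark_noise_sd=0.0,
        amplitude_by_class={c: 0.0 for c in cosa.CATEGORIES})
    rng = np.random.default_rng(0)
    centerline = synthgen.make_waveform(cosa.Category.STRAIGHT, params,
                                        rng, psi=0.0)
    return params, centerline
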