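import numpy as np
import pytest

from rexmap import synthetic


@pytest.fixture(scope="session")
def small_model():
    """A small but fully featured planted model (fast to sample)."""
    return synthetic.make_ground_truth_msm(
        n_micro=200, n_macro=8, p_stay=0.95, seed=11
    )


@pytest.fixture(scope="session")
def small_paths(small_model):
    return synthetic.sample_state_paths(
        small_model, n_paths=50, path_length=1000, seed=12
    )


@pytest.fixture(scope="session")
def small_emissions(small_model, small_paths):
    spec = synthetic.default_emission_spec(small_model, seed=11)
    frames, shifts, hbonds = synthetic.emit_observables(
        small_paths, small_model, spec, seed=13
    )
    return spec, shifts, hbonds


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
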