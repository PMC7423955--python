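import numpy as np
import pytest

from fepkit.synthetic import ToyPotentialSpec, generate_transformation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def harmonic_spec():
    """Default toy transformation: k 1 -> 2 kcal/mol/A^2 at 300 K."""
    return ToyPotentialSpec(
        kind="harmonic", spring_constant_initial=1.0, spring_constant_final=2.0
    )


@pytest.fixture(scope="session")
def toy_windows(harmonic_spec):
    """A small seeded transformation reused across estimator tests."""
    return generate_transformation(
        harmonic_spec, n_windows=5, n_steps_per_window=4000, seed=7
    )
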