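import numpy as np
import pytest

from p31shift import synthetic
from p31shift.synthetic import GeneratorConfig


@pytest.fixture(scope="session")
def library():
    return synthetic.default_library()


@pytest.fixture(scope="session")
def noiseless_records(library):
    """400 additive, noise-free molecules: the exact-recovery oracle set."""
    cfg = GeneratorConfig(n_molecules=400, seed=2, noise_sd=0.0)
    return synthetic.generate(cfg, library)


@pytest.fixture(scope="session")
def noisy_records(library):
    cfg = GeneratorConfig(n_molecules=300, seed=3, noise_sd=2.0)
    return synthetic.generate(cfg, library)


@pytest.fixture(scope="session")
def small_records(library):
    cfg = GeneratorConfig(n_molecules=40, seed=11, noise_sd=1.0)
    return synthetic.generate(cfg, library)


def shifts(records):
    return np.array([r.shift_ppm for r in records])


def graphs(records):
    return [r.graph for r in records]
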