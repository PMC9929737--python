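import numpy as np
import pytest
from hypothesis import settings

from clampdyn.collective_variables import com_distance
from clampdyn.synthetic_data import (
    gen_detachment_traj, gen_dimer_breathing, gen_toy_complex,
    linear_separation,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_complex():
    return gen_toy_complex(seed=0)


@pytest.fixture(scope="session")
def detachment(toy_complex):
    d0 = com_distance(toy_complex.structure, toy_complex.structure.positions,
                      toy_complex.cv_spec)
    return gen_detachment_traj(toy_complex,
                               linear_separation(d0, d0 + 20.0, 80), seed=0)


@pytest.fixture(scope="session")
def dimer():
    lobe_a = gen_toy_complex(20, 16, seed=0)
    lobe_b = gen_toy_complex(20, 16, seed=1)
    return gen_dimer_breathing(lobe_a, lobe_b, amplitude=2.0, n_frames=200,
                               noise_sd=0.2, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
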