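import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def draw_params(rng, n, *, constitutive=False):
    """Random valid parameter sets spanning the realistic ranges."""
    out = []
    for _ in range(n):
        kd = 10.0 ** rng.uniform(-10, -4)
        eps = rng.uniform(0.02, 1.0)
        gamma = 10.0 ** rng.uniform(0, 4)
        eps_r0 = rng.uniform(0.0, 0.9) if constitutive else 0.0
        out.append((kd, eps, gamma, eps_r0))
    return out


def conc_grid(kd, n=100, decades=4):
    """Log grid spanning kd*10^-decades .. kd*10^+decades, plus zero."""
    return np.geomspace(kd * 10.0 ** -decades, kd * 10.0 ** decades, n)
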