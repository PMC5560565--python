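import numpy as np
import pytest

from octlayers import PhantomParams, generate_phantom
from octlayers.graphseg import ConstraintSpec


def noiseless_overrides():
    """Parameter overrides switching every stochastic corruption off."""
    return dict(speckle_shape=np.inf, additive_sigma=0.0,
                jitter_sigma_voxels=0.0, undulation_amplitude_um=0.0,
                tilt_um=0.0, n_vessels=0)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Flat, noise-free healthy phantom (truth surfaces are z-constant
    outside the optic nerve head)."""
    params = PhantomParams(**noiseless_overrides())
    return generate_phantom(params, seed=1) + (params,)


def random_instance(seed):
    """A small random solver instance (costs, constraints) with a raw
    configuration count small enough for exhaustive enumeration."""
    r = np.random.default_rng(seed)
    n_surf = int(r.integers(1, 4))
    b = int(r.integers(1, 3))
    x = int(r.integers(2, 4)) if b > 1 else int(r.integers(2, 6))
    z = int(r.integers(4, 10))
    costs = [r.integers(0, 20, (b, x, z)) for _ in range(n_surf)]
    pairs = []
    for i in range(n_surf - 1):
        m = int(r.integers(0, 3))
        pairs.append((i, i + 1, m, m + int(r.integers(0, 4))))
    spec = ConstraintSpec(smoothness_x=int(r.integers(0, 3)),
                          smoothness_b=int(r.integers(0, 4)), pairs=pairs)
    return costs, spec
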