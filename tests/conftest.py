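import numpy as np
import pytest

from relvox import PhantomConfig, generate_cohort
from relvox.layers import Dense, ELU, Flatten, MaxPool3D, Network, Sigmoid, build_network


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-cubed, 6+6-subject lesion cohort shared across tests."""
    from dataclasses import replace

    config = replace(PhantomConfig(), grid_shape=(16, 16, 16), lesion_radius_range=(1.0, 2.0))
    return generate_cohort(config, 6, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dense_net(widths, rng, bias=False, input_is_flat=True):
    """Random all-dense network (flatten+dense stack+sigmoid) over a 3D input.

    ``widths`` are the hidden/output sizes; the last must be 1.
    """
    assert widths[-1] == 1
    shape = (widths[0], 1, 1)
    layers = [Flatten()]
    prev = widths[0]
    for w in widths[1:]:
        d = Dense(prev, w)
        d.W = rng.normal(size=(w, prev))
        d.b = rng.normal(size=w) if bias else np.zeros(w)
        layers.append(d)
        prev = w
    layers.append(Sigmoid())
    return Network(layers, shape)
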