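import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrkit.summary_io import HarmonizedInstrument

logging.getLogger("mrkit").setLevel(logging.ERROR)

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def make_instruments(g, sg, G, sG, ids=None):
    g, sg, G, sG = (np.asarray(a, dtype=float) for a in (g, sg, G, sG))
    ids = ids or [f"rs{j + 1}" for j in range(len(g))]
    return [HarmonizedInstrument(ids[j], float(g[j]), float(sg[j]),
                                 float(G[j]), float(sG[j]))
            for j in range(len(g))]


def random_instruments(rng, n=10, theta=0.2):
    """A generic random instrument set with heterogeneous precision."""
    g = rng.uniform(0.02, 0.08, n)
    sg = rng.uniform(0.002, 0.006, n)
    sG = rng.uniform(0.01, 0.05, n)
    G = theta * g + rng.standard_normal(n) * sG
    return make_instruments(g, sg, G, sG)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def instruments(rng):
    return random_instruments(rng, n=12)
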