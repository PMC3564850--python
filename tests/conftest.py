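import random

import matplotlib
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return random.Random(20260930)


@pytest.fixture
def worked_network():
    """The two-source network used throughout: S1 undirected {A-B, B-C},
    S2 directed {A->B, C->D}."""
    from priorank.integrate import integrate_networks
    from priorank.io import NETWORK, Record, SourceTable

    s1 = SourceTable("S1", NETWORK, ("n1", "n2"), (),
                     (Record(("A", "B")), Record(("B", "C"))))
    s2 = SourceTable("S2", NETWORK, ("n1", "n2"), (),
                     (Record(("A", "B")), Record(("C", "D"))))
    return integrate_networks(
        [s1, s2],
        directedness={"S1": "undirected", "S2": "directed"},
    )
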