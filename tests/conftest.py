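import networkx as nx
import pandas as pd
import pytest

from leadfollow import RecordingSet, SimConfig, simulate


@pytest.fixture
def toy_network():
    """Five-node worked-example network: follower -> leader links
    1->4, 2->4, 3->4, 4->5, 5->1, all weights 1."""
    g = nx.DiGraph()
    for u, v in [("1", "4"), ("2", "4"), ("3", "4"), ("4", "5"), ("5", "1")]:
        g.add_edge(u, v, weight=1)
    return g


@pytest.fixture
def three_row_recordings():
    return RecordingSet.from_records(
        [
            (pd.Timestamp("2008-05-01 22:00:00"), "0000000001", "B01"),
            (pd.Timestamp("2008-05-01 23:30:00"), "0000000002", "B01"),
            (pd.Timestamp("2008-05-02 01:00:00"), "0000000003", "B02"),
        ]
    )


@pytest.fixture(scope="session")
def separable_run():
    """Simulated season in the separable regime: short delays, widely
    spaced unrelated reads, no swarming, no noise, no occupation."""
    cfg = SimConfig(
        n_bats=20,
        n_boxes=10,
        n_nights=60,
        swarming=False,
        noise_rate=0.0,
        p_occupy=0.0,
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def default_run():
    """Simulated season under the default conditions (swarming, noise,
    occupation all active)."""
    return simulate(SimConfig(seed=7))
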