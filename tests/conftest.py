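import numpy as np
import pandas as pd
import pytest

from evofoodweb import run
from evofoodweb.analysis import TrimmedWeb
from evofoodweb.community import FoodWebSnapshot


def make_snapshot(flows, attack=None, traits=None, resource_B=10.0,
                  e_plant=1.0, e_animal=1.0, t=0.0) -> FoodWebSnapshot:
    """Build a snapshot directly from matrices (for analysis unit tests).

    With e = 1 the flow matrix doubles as the contribution matrix, so
    tests can state cutoff arithmetic in plain numbers.
    """
    flows = np.asarray(flows, dtype=float)
    n = flows.shape[0]
    if attack is None:
        attack = flows.copy()
    if traits is None:
        traits = pd.DataFrame(
            {
                "id": np.arange(1, n + 1),
                "m": np.full(n, 10.0),
                "f": np.ones(n),
                "s": np.ones(n),
                "B": np.ones(n),
            }
        )
    return FoodWebSnapshot(
        t=t,
        nodes=traits,
        resource_B=resource_B,
        attack=np.asarray(attack, dtype=float),
        flow=flows,
        e_plant=e_plant,
        e_animal=e_animal,
    )


def web_from_edges(n_nodes, edges, flows=None) -> TrimmedWeb:
    """Build a trimmed web straight from an edge list (consumer -> prey)."""
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    for i, j in edges:
        adj[i, j] = True
    if flows is None:
        flows = adj[1:, :].astype(float)
    nodes = pd.DataFrame(
        {
            "id": np.arange(1, n_nodes),
            "m": 10.0 ** np.arange(1, n_nodes),
            "f": np.ones(n_nodes - 1),
            "s": np.ones(n_nodes - 1),
            "B": np.ones(n_nodes - 1),
        }
    )
    return TrimmedWeb(nodes=nodes, adjacency=adj, rule="manual", fraction=0.0,
                      flows=np.asarray(flows, dtype=float))


@pytest.fixture(scope="session")
def assembly_run():
    """One moderately long assembly run shared across tests.

    Baseline competition parameters (c_food = 0.8, c_intra = 1.4); the
    horizon is long enough for several trophic levels and hundreds of
    speciation events while staying desk-scale.
    """
    return run(t_end=4e6, seed=1, snapshot_start=1e6, snapshot_interval=5e5)
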