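import math

import numpy as np
import pandas as pd
import pytest

from moha import CellTable, MolecularStateAssignment, NeighborGraph


def random_fixture(rng: np.random.Generator, n_max: int = 50):
    """A small random tissue: positions, areas, a molecular assignment over
    1–4 states on a 2-node panel, and the touching graph inputs.

    Returns (table, assignment) with everything small enough for the
    brute-force oracles.
    """
    n = int(rng.integers(2, n_max + 1))
    xy = rng.uniform(0, math.sqrt(n) * 4.0, size=(n, 2))
    areas = rng.uniform(2.0, 20.0, size=n)
    ids = [f"c{i}" for i in range(n)]
    df = pd.DataFrame(
        {"cell_id": ids, "sample_id": "s", "x": xy[:, 0], "y": xy[:, 1],
         "cell_area": areas}
    )
    table = CellTable("s", df)

    n_state_vals = int(rng.integers(1, 5))
    vecs = {}
    for s in range(n_state_vals):
        key = f"{s // 3}{s % 3}"
        vecs[key] = (s // 3, s % 3)
    keys = list(vecs)
    states = {cid: keys[int(rng.integers(len(keys)))] for cid in ids}
    assignment = MolecularStateAssignment(
        pathway="p", n_states=3, states=states,
        level_vectors={k: vecs[k] for k in set(states.values())},
    )
    return table, assignment


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def make_graph():
    def _make(ids, pairs):
        return NeighborGraph(list(ids), {tuple(p) for p in pairs})

    return _make
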