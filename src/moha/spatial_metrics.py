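"""Spatial diversity metrics combining molecular states with tissue topology.

Four metrics are computed from a molecular state assignment and the
touching-cell graph:

* cell coordination number entropy — Shannon index of the coordination
  number distribution; purely spatial, no molecular information;
* cell family — per cell, the number of touching neighbors sharing its
  exact molecular state (0..Z_max);
* cell neighbor — per cell, one state per distinct molecular state present
  in its neighborhood, the state being the count of neighbors in it;
* cell social — sizes of maximal connected groups of touching same-state
  cells.

Cells without an assigned molecular state are removed from the graph
(edges deleted) before any of these are computed: a cell of unknown state
can neither match nor mismatch its neighbors.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .pathway_states import MolecularStateAssignment, StateDistribution
from .spatial_graph import NeighborGraph


def restrict_to_assigned(
    assignment: MolecularStateAssignment, graph: NeighborGraph
) -> NeighborGraph:
    """Drop unassigned cells (and their edges) from the graph."""
    return graph.subgraph(assignment.states.keys())


def _check(assignment: MolecularStateAssignment, graph: NeighborGraph) -> NeighborGraph:
    if assignment.n_assigned == 0:
        raise ValueError("no assigned cells")
    g = restrict_to_assigned(assignment, graph)
    if g.n_cells == 0:
        raise ValueError("graph holds no assigned cells")
    return g


def cell_family_states(
    assignment: MolecularStateAssignment, graph: NeighborGraph
) -> dict:
    """Per-cell family state: the count of touching neighbors in the same
    molecular state.  Isolated cells have family state 0."""
    g = _check(assignment, graph)
    states = assignment.states
    fam = {c: 0 for c in g.cell_ids}
    for a, b in g.edges:
        if states[a] == states[b]:
            fam[a] += 1
            fam[b] += 1
    return fam


def cell_family_distribution(
    assignment: MolecularStateAssignment, graph: NeighborGraph
) -> StateDistribution:
    """Frequency distribution of family states over k = 0..Z_max; the
    heterogeneity denominator is ln(Z_max + 1)."""
    g = _check(assignment, graph)
    fam = cell_family_states(assignment, graph)
    counts = Counter(fam.values())
    n = len(fam)
    probs = {int(k): c / n for k, c in sorted(counts.items())}
    return StateDistribution(probabilities=probs, n_states_max=g.z_max + 1)


def cell_neighbor_states(
    assignment: MolecularStateAssignment, graph: NeighborGraph
) -> list[int]:
    """Pooled neighbor states: for every cell and every distinct molecular
    state among its neighbors, the count of neighbors in that state.  Cells
    with no neighbors emit nothing."""
    g = _check(assignment, graph)
    states = assignment.states
    emitted: list[int] = []
    for cell, nbrs in g.neighbors().items():
        if not nbrs:
            continue
        emitted.extend(Counter(states[b] for b in nbrs).values())
    return emitted


def cell_neighbor_distribution(
    assignment: MolecularStateAssignment, graph: NeighborGraph
) -> StateDistribution:
    """Distribution of pooled neighbor states over counts 1..Z_max,
    normalized by ln(Z_max + 1)."""
    g = _check(assignment, graph)
    emitted = cell_neighbor_states(assignment, graph)
    if not emitted:
        raise ValueError("no cell has neighbors: neighbor metric undefined")
    counts = Counter(emitted)
    n = len(emitted)
    probs = {int(k): c / n for k, c in sorted(counts.items())}
    return StateDistribution(probabilities=probs, n_states_max=g.z_max + 1)


def cell_social_groups(
    assignment: MolecularStateAssignment, graph: NeighborGraph
) -> list[list]:
    """Partition assigned cells into social groups: maximal connected sets
    of touching cells sharing one molecular state.  Singletons (monomers)
    are valid groups."""
    g = _check(assignment, graph)
    ids = g.cell_ids
    index = {c: i for i, c in enumerate(ids)}
    states = assignment.states
    same = [(index[a], index[b]) for a, b in g.edges if states[a] == states[b]]
    n = len(ids)
    if same:
        rows, cols = zip(*same)
        adj = coo_matrix((np.ones(len(same)), (rows, cols)), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n)
    groups: dict[int, list] = {}
    for cid, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(cid)
    return list(groups.values())


def max_social_states(n_cells: int) -> int:
    """Largest N_s with N_s(N_s+1)/2 ≤ N_c: the number of distinct group
    sizes that could coexist among N_c cells, Int((√(8·N_c+1) − 1)/2)."""
    if n_cells < 1:
        raise ValueError("need at least one cell")
    ns = (math.isqrt(8 * n_cells + 1) - 1) // 2
    return int(ns)


def cell_social_distribution(groups: list[list], n_cells: int) -> StateDistribution:
    """Distribution over social group sizes, each group one observation;
    normalized by ln(N_s) with N_s = max_social_states(n_cells)."""
    if not groups:
        raise ValueError("empty partition")
    sizes = Counter(len(g) for g in groups)
    total = len(groups)
    probs = {int(s): c / total for s, c in sorted(sizes.items())}
    return StateDistribution(probabilities=probs, n_states_max=max_social_states(n_cells))


def spatial_entropy_and_heterogeneity(dist: StateDistribution) -> tuple[float, float]:
    """Shannon entropy (nats) and its normalization by ln(max state count)."""
    from .molecular_metrics import heterogeneity, shannon_entropy

    return shannon_entropy(dist), heterogeneity(dist)


def coordination_entropy(dist: StateDistribution) -> float:
    """Shannon entropy of the coordination-number distribution, reported
    unnormalized."""
    from .molecular_metrics import shannon_entropy

    return shannon_entropy(dist)


@dataclasses.dataclass
class SpatialMetrics:
    """All spatial diversity metrics of one sample."""

    coordination_entropy: float
    family_entropy: float
    family_heterogeneity: float
    neighbor_entropy: float
    neighbor_heterogeneity: float
    social_entropy: float
    social_heterogeneity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "CellCoordinationNumberEntropy": self.coordination_entropy,
            "CellFamilyEntropy": self.family_entropy,
            "CellFamilyHeterogeneity": self.family_heterogeneity,
            "CellNeighborEntropy": self.neighbor_entropy,
            "CellNeighborHeterogeneity": self.neighbor_heterogeneity,
            "CellSocialEntropy": self.social_entropy,
            "CellSocialHeterogeneity": self.social_heterogeneity,
        }


def compute_spatial_metrics(
    assignment: MolecularStateAssignment, graph: NeighborGraph
) -> SpatialMetrics:
    """Compute all four spatial metrics on the assigned-cell subgraph."""
    from .spatial_graph import coordination_distribution

    g = _check(assignment, graph)
    coord = coordination_distribution(g)
    fam = cell_family_distribution(assignment, graph)
    fam_e, fam_h = spatial_entropy_and_heterogeneity(fam)
    try:
        nbr = cell_neighbor_distribution(assignment, graph)
        nbr_e, nbr_h = spatial_entropy_and_heterogeneity(nbr)
    except ValueError:  # all cells isolated
        nbr_e, nbr_h = 0.0, 0.0
    groups = cell_social_groups(assignment, graph)
    soc = cell_social_distribution(groups, g.n_cells)
    soc_e, soc_h = spatial_entropy_and_heterogeneity(soc)
    return SpatialMetrics(
        coordination_entropy=coordination_entropy(coord),
        family_entropy=fam_e,
        family_heterogeneity=fam_h,
        neighbor_entropy=nbr_e,
        neighbor_heterogeneity=nbr_h,
        social_entropy=soc_e,
        social_heterogeneity=soc_h,
    )
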