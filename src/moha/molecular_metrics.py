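"""Molecular diversity metrics: Shannon entropy, normalized heterogeneity,
and pairwise-distance disparity over the molecular state distribution.

All entropies are in nats.  Heterogeneity divides the entropy by the
natural log of the maximum possible number of states, mapping it to [0, 1];
disparity additionally weights state pairs by their squared node-level
distance, so it separates distributions whose states are nearly identical
from those spread over distant corners of state space.
"""

from __future__ import annotations

import numpy as np

from .pathway_states import StateDistribution


def shannon_entropy(dist: StateDistribution) -> float:
    """Shannon diversity index −Σ_i P_i ln P_i over the observed states."""
    p = np.fromiter(dist.probabilities.values(), dtype=float)
    return float(-np.sum(p * np.log(p)))


def heterogeneity(dist: StateDistribution) -> float:
    """Entropy normalized by ln(max possible states); 0 when only one state
    is possible.  Ranges from 0 (all cells one state) to 1 (uniform over the
    maximum number of states)."""
    if dist.n_states_max < 1:
        raise ValueError("n_states_max must be >= 1")
    if dist.n_states_max == 1:
        return 0.0
    return shannon_entropy(dist) / float(np.log(dist.n_states_max))


def state_distance_sq(levels_i: tuple[int, ...], levels_j: tuple[int, ...]) -> float:
    """Squared molecular distance: Σ_n (M_n,i − M_n,j)² across pathway nodes."""
    if len(levels_i) != len(levels_j):
        raise ValueError("level vectors differ in length")
    a = np.asarray(levels_i, dtype=float)
    b = np.asarray(levels_j, dtype=float)
    return float(np.sum((a - b) ** 2))


def molecular_disparity(dist: StateDistribution) -> float:
    """Frequency-weighted disparity Σ_{i<j} P_i P_j d(i,j)².

    States absent from the sample carry zero frequency and contribute
    nothing, so the sum runs over observed states only.
    """
    if dist.level_vectors is None:
        raise ValueError("distribution lacks level vectors; disparity undefined")
    keys = list(dist.probabilities)
    p = np.array([dist.probabilities[k] for k in keys], dtype=float)
    m = np.array([dist.level_vectors[k] for k in keys], dtype=float)
    if len(keys) == 1:
        return 0.0
    # d²(i,j) via the Gram expansion; pair sum = ½ Σ_ij P_i P_j d²(i,j)
    sq = np.sum(m * m, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (m @ m.T)
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum(d2, 0.0)
    return float(0.5 * p @ d2 @ p)
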