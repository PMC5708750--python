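"""Discrete molecular pathway states.

A cell's molecular state is the concatenation of its ordinal levels across
the pathway's measurable nodes, taken in the pathway's fixed node order.
Cells missing any node level are left unassigned and excluded from state
counts — no level is imputed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cell_table_io import PathwayDefinition


def state_key(levels: tuple[int, ...], n_states: int) -> str:
    """Canonical text key for a level vector: one character per node for up
    to 10 levels (e.g. ``"2122202222211222"``), hyphen-separated otherwise."""
    if n_states <= 10:
        return "".join(str(v) for v in levels)
    return "-".join(str(v) for v in levels)


@dataclasses.dataclass
class MolecularStateAssignment:
    """Per-cell discrete pathway states for one sample.

    ``states`` maps cell_id → state key for assigned cells only;
    ``level_vectors`` maps state key → the node-level tuple behind it.
    """

    pathway: str
    n_states: int
    states: dict[object, str]
    level_vectors: dict[str, tuple[int, ...]]
    n_unassigned: int = 0

    @property
    def n_assigned(self) -> int:
        return len(self.states)

    @property
    def n_pathway_nodes(self) -> int:
        return len(next(iter(self.level_vectors.values()))) if self.level_vectors else 0

    @property
    def n_max_states(self) -> int:
        return max_molecular_states(self.n_states, self.n_pathway_nodes, self.n_assigned)


@dataclasses.dataclass
class StateDistribution:
    """Normalized frequencies over discrete states — the common input of all
    Shannon-index computations.

    ``n_states_max`` is the normalization denominator source: the maximum
    number of states the system could exhibit.  ``level_vectors`` is carried
    when states are molecular pathway states (needed for disparity).
    """

    probabilities: dict[object, float]
    n_states_max: int
    level_vectors: dict[str, tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        if not self.probabilities:
            raise ValueError("empty state distribution")
        total = float(sum(self.probabilities.values()))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, not 1")
        if any(p <= 0 for p in self.probabilities.values()):
            raise ValueError("probabilities must be positive")


def max_molecular_states(n_states: int, n_nodes: int, n_cells: int) -> int:
    """Maximum number of molecular states a sample can exhibit.

    The combinatorial ceiling is n_states**n_nodes (exact integer
    arithmetic: a 16-node pathway with three levels allows 3^16 ≈ 4.3e7
    states); when the sample holds fewer cells than that, the cell count is
    the operative maximum.
    """
    if n_states < 1 or n_nodes < 1 or n_cells < 1:
        raise ValueError("all arguments must be >= 1")
    return min(n_states ** n_nodes, n_cells)


def assign_states(
    ordinal: pd.DataFrame,
    pathway: PathwayDefinition,
    n_states: int = 3,
) -> MolecularStateAssignment:
    """Assign each cell its pathway state from the ordinal level table.

    ``ordinal`` is indexed by cell_id with one column per panel key.  Cells
    with a missing level at any pathway node are unassigned.
    """
    missing_nodes = [k for k in pathway.keys if k not in ordinal.columns]
    if missing_nodes:
        raise KeyError(
            f"pathway {pathway.name!r} nodes absent from the panel: {missing_nodes}"
        )
    sub = ordinal[pathway.keys]
    complete = sub.notna().all(axis=1)
    levels = sub[complete].to_numpy()
    if levels.size and not np.all(levels == np.floor(levels)):
        raise ValueError("ordinal table contains non-integer levels")
    levels = levels.astype(int)
    if levels.size and (levels.min() < 0 or levels.max() >= n_states):
        raise ValueError("ordinal levels outside [0, n_states)")

    states: dict[object, str] = {}
    level_vectors: dict[str, tuple[int, ...]] = {}
    for cell_id, row in zip(sub.index[complete], levels):
        vec = tuple(int(v) for v in row)
        key = state_key(vec, n_states)
        states[cell_id] = key
        level_vectors.setdefault(key, vec)
    return MolecularStateAssignment(
        pathway=pathway.name,
        n_states=n_states,
        states=states,
        level_vectors=level_vectors,
        n_unassigned=int((~complete).sum()),
    )


def state_frequencies(assignment: MolecularStateAssignment) -> StateDistribution:
    """Observed molecular-state frequencies, with the maximum-state count
    attached for heterogeneity normalization."""
    if assignment.n_assigned == 0:
        raise ValueError("no assigned cells: empty sample")
    counts: dict[str, int] = {}
    for key in assignment.states.values():
        counts[key] = counts.get(key, 0) + 1
    n = assignment.n_assigned
    probs = {k: c / n for k, c in sorted(counts.items())}
    return StateDistribution(
        probabilities=probs,
        n_states_max=assignment.n_max_states,
        level_vectors=assignment.level_vectors,
    )
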