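"""Null models decoupling molecular states from cell positions.

Two routes quantify how far a tissue's spatial metrics sit from what a
random arrangement of the same molecular states over the same cell
positions would give:

* Monte-Carlo: permute the state labels uniformly over the cell positions
  (the molecular state multiset is preserved exactly) and recompute the
  spatial metrics; repeated R times (default 120) per sample.
* Analytic (cell family only): the expected family-state distribution
  under random arrangement, summing binomial configuration counts
  N_sk = Σ_j Σ_i C(Z_j, k) (1 − P_mi)^(Z_j − k) P_mi^(k+1) over cells j and
  molecular states i, normalized over k = 0..Z_max.  The binomial model
  treats neighbor states as independent draws from the molecular
  frequencies, so it is the infinite-population limit of the permutation
  ensemble: the two agree up to O(1/N_c) finite-sample terms.

The permutation ensemble is evaluated by a vectorized engine operating on
integer state codes; it is exactly equivalent to permuting the assignment
and recomputing the metrics object-by-object (a property the test suite
checks), just much faster for large R.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln

from .molecular_metrics import heterogeneity, shannon_entropy
from .pathway_states import MolecularStateAssignment, StateDistribution, state_frequencies
from .spatial_graph import NeighborGraph
from .spatial_metrics import compute_spatial_metrics, max_social_states, restrict_to_assigned

DEFAULT_PERMUTATIONS = 120

SPATIAL_METRIC_NAMES = (
    "CellCoordinationNumberEntropy",
    "CellFamilyEntropy",
    "CellFamilyHeterogeneity",
    "CellNeighborEntropy",
    "CellNeighborHeterogeneity",
    "CellSocialEntropy",
    "CellSocialHeterogeneity",
)


@dataclasses.dataclass
class NullEnsembleResult:
    """Permutation ensemble for one spatial metric."""

    metric: str
    observed: float
    values: np.ndarray  # length R
    mean: float
    sd: float
    z: float


def permute_states(
    assignment: MolecularStateAssignment,
    rng: np.random.Generator | int,
) -> MolecularStateAssignment:
    """Uniformly permute the molecular state labels over cell positions.

    The state multiset — hence every molecular metric — is unchanged; only
    which cell carries which state varies.  Reproducible given a seed.
    """
    if assignment.n_assigned < 2:
        raise ValueError("need at least 2 assigned cells to permute")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cells = list(assignment.states.keys())
    labels = list(assignment.states.values())
    perm = rng.permutation(len(labels))
    return MolecularStateAssignment(
        pathway=assignment.pathway,
        n_states=assignment.n_states,
        states={c: labels[p] for c, p in zip(cells, perm)},
        level_vectors=assignment.level_vectors,
        n_unassigned=assignment.n_unassigned,
    )


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log(p)))


class _PermutationEngine:
    """Spatial metrics on integer state codes; one permutation = one
    shuffled code vector, evaluated without rebuilding any objects."""

    def __init__(self, assignment: MolecularStateAssignment, graph: NeighborGraph):
        g = restrict_to_assigned(assignment, graph)
        if set(assignment.states) - set(g.cell_ids):
            raise ValueError("graph does not cover all assigned cells")
        # cell order must match permute_states (insertion order of states)
        self.cells = list(assignment.states.keys())
        index = {c: i for i, c in enumerate(self.cells)}
        keys = sorted(set(assignment.states.values()))
        code = {k: i for i, k in enumerate(keys)}
        self.codes0 = np.array([code[assignment.states[c]] for c in self.cells])
        self.n_codes = len(keys)
        self.n = len(self.cells)
        if g.edges:
            ei, ej = zip(*g.edges)
            self.ei = np.array([index[c] for c in ei])
            self.ej = np.array([index[c] for c in ej])
        else:
            self.ei = np.empty(0, dtype=int)
            self.ej = np.empty(0, dtype=int)
        z = np.zeros(self.n, dtype=int)
        np.add.at(z, self.ei, 1)
        np.add.at(z, self.ej, 1)
        self.z_max = int(z.max()) if self.n else 0
        self.coordination_entropy = _entropy_from_counts(np.bincount(z))
        self._log_zmax1 = np.log(self.z_max + 1) if self.z_max > 0 else None
        self._ns = max_social_states(self.n)

    def metrics(self, codes: np.ndarray, wanted: tuple[str, ...]) -> dict[str, float]:
        out: dict[str, float] = {}
        if "CellCoordinationNumberEntropy" in wanted:
            out["CellCoordinationNumberEntropy"] = self.coordination_entropy
        same = codes[self.ei] == codes[self.ej]
        if any(m.startswith("CellFamily") for m in wanted):
            fam = np.zeros(self.n, dtype=int)
            np.add.at(fam, self.ei[same], 1)
            np.add.at(fam, self.ej[same], 1)
            e = _entropy_from_counts(np.bincount(fam))
            out["CellFamilyEntropy"] = e
            out["CellFamilyHeterogeneity"] = (
                e / self._log_zmax1 if self._log_zmax1 else 0.0
            )
        if any(m.startswith("CellNeighbor") for m in wanted):
            center = np.concatenate([self.ei, self.ej])
            nbr_state = np.concatenate([codes[self.ej], codes[self.ei]])
            if center.size:
                _, emitted = np.unique(center * self.n_codes + nbr_state, return_counts=True)
                e = _entropy_from_counts(np.bincount(emitted))
            else:
                e = 0.0
            out["CellNeighborEntropy"] = e
            out["CellNeighborHeterogeneity"] = (
                e / self._log_zmax1 if self._log_zmax1 else 0.0
            )
        if any(m.startswith("CellSocial") for m in wanted):
            adj = coo_matrix(
                (np.ones(int(same.sum())), (self.ei[same], self.ej[same])),
                shape=(self.n, self.n),
            )
            _, labels = connected_components(adj, directed=False)
            sizes = np.bincount(labels)
            e = _entropy_from_counts(np.bincount(sizes[sizes > 0]))
            out["CellSocialEntropy"] = e
            out["CellSocialHeterogeneity"] = (
                e / np.log(self._ns) if self._ns > 1 else 0.0
            )
        return out


def null_ensemble(
    assignment: MolecularStateAssignment,
    graph: NeighborGraph,
    metrics: tuple[str, ...] = SPATIAL_METRIC_NAMES,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
) -> dict[str, NullEnsembleResult]:
    """Permutation null distribution for the requested spatial metrics.

    Returns one :class:`NullEnsembleResult` per metric with the observed
    value, the R permutation values, their mean/SD, and the z-score of the
    observed value against the ensemble (NaN when the ensemble SD is 0).
    """
    if n_permutations < 2:
        raise ValueError("need at least 2 permutations")
    unknown = [m for m in metrics if m not in SPATIAL_METRIC_NAMES]
    if unknown:
        raise KeyError(f"unknown spatial metrics: {unknown}")
    if assignment.n_assigned < 2:
        raise ValueError("need at least 2 assigned cells")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    observed = compute_spatial_metrics(assignment, graph).as_dict()
    engine = _PermutationEngine(assignment, graph)
    values = {m: np.empty(n_permutations) for m in metrics}
    for r in range(n_permutations):
        perm = rng.permutation(engine.n)
        sm = engine.metrics(engine.codes0[perm], metrics)
        for m in metrics:
            values[m][r] = sm[m]
    out = {}
    for m in metrics:
        v = values[m]
        mean, sd = float(v.mean()), float(v.std(ddof=1))
        z = (observed[m] - mean) / sd if sd > 0 else float("nan")
        out[m] = NullEnsembleResult(m, observed[m], v, mean, sd, float(z))
    return out


def probability_based_family(
    assignment: MolecularStateAssignment,
    graph: NeighborGraph,
) -> tuple[StateDistribution, float, float]:
    """Analytic expected cell-family distribution under random arrangement.

    For family state k the configuration count pools binomial terms over
    every cell j (coordination number Z_j) and molecular state i (frequency
    P_mi); frequencies follow by normalization and the family entropy /
    heterogeneity are computed from them exactly as for the observed
    distribution (denominator ln(Z_max + 1)).  Binomial coefficients are
    evaluated in log space.

    Returns (distribution, entropy, heterogeneity).
    """
    mol = state_frequencies(assignment)
    p = np.fromiter(mol.probabilities.values(), dtype=float)
    g = restrict_to_assigned(assignment, graph)
    if g.n_cells == 0:
        raise ValueError("graph holds no assigned cells")
    z = np.fromiter(g.degrees().values(), dtype=int)
    z_max = g.z_max
    ns_k = np.zeros(z_max + 1)
    log_p = np.log(p)
    with np.errstate(divide="ignore"):
        log_q = np.log1p(-p)  # -inf when p == 1, handled below
    for zj, mult in zip(*np.unique(z, return_counts=True)):
        for k in range(int(zj) + 1):
            log_binom = gammaln(zj + 1) - gammaln(zj - k + 1) - gammaln(k + 1)
            with np.errstate(invalid="ignore"):
                terms = (zj - k) * log_q + (k + 1) * log_p + log_binom
            # (1-p)^0 with p == 1 is 1, not exp(0 * -inf)
            terms = np.where(
                (zj - k == 0) & np.isneginf(log_q), (k + 1) * log_p + log_binom, terms
            )
            ns_k[k] += mult * float(np.sum(np.exp(terms[~np.isneginf(terms)])))
    total = ns_k.sum()
    if total <= 0:
        raise ValueError("degenerate configuration count")
    ps_k = ns_k / total
    probs = {int(k): float(v) for k, v in enumerate(ps_k) if v > 0}
    dist = StateDistribution(probabilities=probs, n_states_max=z_max + 1)
    ent = shannon_entropy(dist)
    het = heterogeneity(dist)
    return dist, ent, het
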