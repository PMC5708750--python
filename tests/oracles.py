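"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops over plain Python data, kept
deliberately free of the package's vectorized/indexed code paths so the two
routes can disagree.
"""

from __future__ import annotations

import math
from collections import Counter

import networkx as nx


def entropy(probs) -> float:
    return -sum(p * math.log(p) for p in probs if p > 0)


def heterogeneity(probs, n_max: int) -> float:
    if n_max <= 1:
        return 0.0
    return entropy(probs) / math.log(n_max)


def disparity(probs_by_state: dict, levels_by_state: dict) -> float:
    keys = list(probs_by_state)
    total = 0.0
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = levels_by_state[keys[i]], levels_by_state[keys[j]]
            d2 = sum((x - y) ** 2 for x, y in zip(a, b))
            total += probs_by_state[keys[i]] * probs_by_state[keys[j]] * d2
    return total


def approx_edges_allpairs(ids, xs, ys, areas, d_critical=1.31) -> set:
    """O(N²) scan of the equivalent-circle touching criterion."""
    edges = set()
    rs = [math.sqrt(a / math.pi) for a in areas]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = math.hypot(xs[i] - xs[j], ys[i] - ys[j])
            if d <= d_critical * (rs[i] + rs[j]):
                edges.add(frozenset((ids[i], ids[j])))
    return edges


def exact_edges_allpairs(pixels: dict) -> set:
    """All-pairs pixel comparison, Chebyshev <= 1."""
    ids = list(pixels)
    edges = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            touching = False
            for (r1, c1) in pixels[ids[i]]:
                for (r2, c2) in pixels[ids[j]]:
                    if max(abs(int(r1) - int(r2)), abs(int(c1) - int(c2))) <= 1:
                        touching = True
                        break
                if touching:
                    break
            if touching:
                edges.add(frozenset((ids[i], ids[j])))
    return edges


def degrees(ids, edges) -> dict:
    z = {c: 0 for c in ids}
    for e in edges:
        a, b = tuple(e)
        z[a] += 1
        z[b] += 1
    return z


def family_states(states: dict, ids, edges) -> dict:
    fam = {c: 0 for c in ids}
    for c in ids:
        for e in edges:
            if c in e:
                (other,) = set(e) - {c}
                if states[other] == states[c]:
                    fam[c] += 1
    return fam


def neighbor_emissions(states: dict, ids, edges) -> list:
    emitted = []
    for c in ids:
        nbr_states = []
        for e in edges:
            if c in e:
                (other,) = set(e) - {c}
                nbr_states.append(states[other])
        emitted.extend(Counter(nbr_states).values())
    return emitted


def social_group_sizes(states: dict, ids, edges) -> Counter:
    """Connected components of the same-state subgraph via networkx."""
    g = nx.Graph()
    g.add_nodes_from(ids)
    for e in edges:
        a, b = tuple(e)
        if states[a] == states[b]:
            g.add_edge(a, b)
    return Counter(len(comp) for comp in nx.connected_components(g))


def max_social_states(n_cells: int) -> int:
    ns = 0
    while (ns + 1) * (ns + 2) // 2 <= n_cells:
        ns += 1
    return ns


def probability_family_dist(pm: list, zs: list) -> list:
    """Direct evaluation of the binomial configuration-count double sum."""
    zmax = max(zs)
    ns_k = [0.0] * (zmax + 1)
    for zj in zs:
        for k in range(zj + 1):
            for p in pm:
                ns_k[k] += math.comb(zj, k) * (1 - p) ** (zj - k) * p ** (k + 1)
    total = sum(ns_k)
    return [v / total for v in ns_k]


def nearest_rank(values, pct) -> float:
    v = sorted(values)
    rank = math.ceil(pct / 100 * len(v))
    rank = min(max(rank, 1), len(v))
    return v[rank - 1]
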