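"""Greedy discovery of significant sub-networks on the weighted PPI graph.

The module score is a weighted boundary-ratio local modularity,

    Q(S) = W_in / (W_in + W_bnd),

where W_in sums w^gamma over edges inside the member set S and W_bnd
sums w^gamma over edges with exactly one end inside. Q is 1 exactly when
S is a whole connected component. Search grows each top-weight seed edge
greedily, adding the neighbor with the largest strictly positive score
increase. Empirical significance comes from repeating the identical
seed-and-expand procedure on networks with the node-level adjusted
p-values permuted (weights recomputed), stratified by module size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .promoter import P_FLOOR


@dataclass
class SearchConfig:
    size_min: int = 5
    size_max: int = 25
    gamma: float = 0.75           # weight exponent of the score
    n_null: int = 1000
    alpha: float = 0.05
    max_seeds: int = 500
    overlap_jaccard_max: float = 0.5
    null_model: str = "rewire"    # "rewire" (degree-preserving) or "permute" (node p')
    seed: int = 0

    def __post_init__(self):
        if self.size_min < 3:
            raise ValueError("size_min must be >= 3")
        if self.n_null < 100:
            raise ValueError("n_null must be >= 100")
        if self.null_model not in ("rewire", "permute"):
            raise ValueError("null_model must be 'rewire' or 'permute'")


@dataclass
class SubNetwork:
    members: frozenset
    score: float
    empirical_p: float
    seed_edge: tuple
    size: int = field(init=False)

    def __post_init__(self):
        self.size = len(self.members)


def local_modularity(network: nx.Graph, members, gamma: float = 1.0) -> float:
    """Weighted boundary-ratio local modularity of a connected node set."""
    members = set(members)
    if not members <= set(network.nodes):
        raise ValueError("members must be nodes of the network")
    if not nx.is_connected(network.subgraph(members)):
        raise ValueError("induced subgraph is not connected")
    w_in = w_bnd = 0.0
    for u, v, w in network.edges(members, data="weight"):
        if u in members and v in members:
            w_in += w**gamma
        else:
            w_bnd += w**gamma
    if w_in + w_bnd == 0.0:
        raise ValueError("score undefined: no incident edge weight")
    return w_in / (w_in + w_bnd)


class _ArrayGraph:
    """Index-based view of the weighted network for fast repeated search."""

    def __init__(self, network: nx.Graph):
        self.nodes = sorted(network.nodes)
        self.pos = {n: i for i, n in enumerate(self.nodes)}
        self.lp = np.array(
            [np.log(max(network.nodes[n]["adjusted_p"], P_FLOOR)) for n in self.nodes]
        )
        edges = sorted(tuple(sorted(e)) for e in network.edges)
        self.eu = np.array([self.pos[a] for a, b in edges], dtype=np.int64)
        self.ev = np.array([self.pos[b] for a, b in edges], dtype=np.int64)
        self.edge_names = edges
        self.base_w = np.array([network.edges[e]["weight"] for e in edges])
        # 2*log(p'_min) denominator of the weight formula: taken from the
        # graph when the builder recorded it, else from the node minimum;
        # permuted-p weights are recomputed on this same scale
        if "log_p_min" in network.graph:
            self.denom = 2.0 * float(network.graph["log_p_min"])
        elif self.lp.min() < 0:
            self.denom = 2.0 * float(self.lp.min())
        else:
            self.denom = None
        self.adj: list[list[tuple[int, int]]] = [[] for _ in self.nodes]
        for ei in range(len(edges)):
            self.adj[self.eu[ei]].append((self.ev[ei], ei))
            self.adj[self.ev[ei]].append((self.eu[ei], ei))

    def weights_for(self, lp: np.ndarray) -> np.ndarray:
        if self.denom is None:
            return self.base_w
        return (lp[self.eu] + lp[self.ev]) / self.denom

    def rewired(self, rng: np.random.Generator) -> "_ArrayGraph":
        """Degree-preserving double-edge-swap copy (node p' kept in place).

        Requires weights to be reconstructable from node p's (``denom``
        set); each swap replaces edges (a,b),(c,d) with (a,d),(c,b)
        unless that creates a self-loop or multi-edge.
        """
        if self.denom is None:
            raise ValueError("rewiring requires significance-derived weights")
        m = len(self.eu)
        eu, ev = self.eu.copy(), self.ev.copy()
        present = {(int(a), int(b)) if a < b else (int(b), int(a)) for a, b in zip(eu, ev)}
        n_done, attempts = 0, 0
        target = 2 * m
        while n_done < target and attempts < 20 * m:
            attempts += 1
            i, j = rng.integers(m, size=2)
            if i == j:
                continue
            a, b = int(eu[i]), int(ev[i])
            c, d = int(eu[j]), int(ev[j])
            if len({a, b, c, d}) < 4:
                continue
            e1 = (a, d) if a < d else (d, a)
            e2 = (c, b) if c < b else (b, c)
            if e1 in present or e2 in present:
                continue
            present.discard((a, b) if a < b else (b, a))
            present.discard((c, d) if c < d else (d, c))
            present.add(e1)
            present.add(e2)
            eu[i], ev[i] = e1
            eu[j], ev[j] = e2
            n_done += 1
        g = object.__new__(_ArrayGraph)
        g.nodes, g.pos, g.lp, g.denom = self.nodes, self.pos, self.lp, self.denom
        g.eu, g.ev = eu, ev
        g.edge_names = [(self.nodes[a], self.nodes[b]) for a, b in zip(eu, ev)]
        g.base_w = g.weights_for(g.lp)
        g.adj = [[] for _ in g.nodes]
        for ei in range(m):
            g.adj[eu[ei]].append((ev[ei], ei))
            g.adj[ev[ei]].append((eu[ei], ei))
        return g


def _expand(g: _ArrayGraph, wg: np.ndarray, strength: np.ndarray, lp: np.ndarray,
            seed_ei: int, size_min: int, size_max: int):
    """Grow one seed edge greedily; returns (member index set, score) or None.

    ``wg`` is w**gamma per edge, ``strength`` its per-node incident sum.
    Candidate gains are maintained incrementally: adding node c changes
    the score to (W_in + a_c) / (W_in + W_bnd + strength_c - a_c) where
    a_c is c's edge weight into the current members.
    """
    u, v = g.eu[seed_ei], g.ev[seed_ei]
    members = {int(u), int(v)}
    w_in = wg[seed_ei]
    w_bnd = strength[u] + strength[v] - 2.0 * wg[seed_ei]
    if w_in + w_bnd == 0.0:
        return None
    score = w_in / (w_in + w_bnd)
    a = {}  # candidate -> weight into members
    for m in (int(u), int(v)):
        for nbr, ei in g.adj[m]:
            if nbr not in members:
                a[nbr] = a.get(nbr, 0.0) + wg[ei]
    while len(members) < size_max and a:
        best, best_score = None, score
        for c, ac in a.items():
            denom = w_in + w_bnd + strength[c] - ac
            s = (w_in + ac) / denom if denom > 0 else 1.0
            if s <= score + 1e-15:
                continue  # only strictly positive score increases qualify
            if (
                best is None
                or s > best_score + 1e-15
                or (abs(s - best_score) <= 1e-15
                    and (lp[c], g.nodes[c]) < (lp[best], g.nodes[best]))
            ):
                best, best_score = c, s
        if best is None:
            break
        ac = a.pop(best)
        w_in += ac
        w_bnd += strength[best] - 2.0 * ac
        score = best_score
        members.add(best)
        for nbr, ei in g.adj[best]:
            if nbr not in members:
                a[nbr] = a.get(nbr, 0.0) + wg[ei]
    if len(members) < size_min:
        return None
    return members, score


def _run_search(g: _ArrayGraph, lp: np.ndarray, config: SearchConfig):
    """Seed-and-expand pass for one weight assignment; list of (members, score, seed)."""
    w = g.weights_for(lp)
    wg = np.maximum(w, 0.0) ** config.gamma
    strength = np.zeros(len(g.nodes))
    np.add.at(strength, g.eu, wg)
    np.add.at(strength, g.ev, wg)
    order = np.lexsort((g.ev, g.eu, -w))[: config.max_seeds]
    results, seen = [], set()
    for ei in order:
        res = _expand(g, wg, strength, lp, int(ei), config.size_min, config.size_max)
        if res is None:
            continue
        members, score = res
        key = frozenset(members)
        if key not in seen:
            seen.add(key)
            results.append((key, score, g.edge_names[ei]))
    return results


def greedy_expand(network: nx.Graph, seed_edge, config: SearchConfig) -> SubNetwork | None:
    """Expand a single seed edge on the observed network (no null model)."""
    g = _ArrayGraph(network)
    e = tuple(sorted(seed_edge))
    if e not in g.edge_names:
        raise ValueError(f"seed edge {seed_edge!r} not in network")
    w = g.weights_for(g.lp)
    wg = np.maximum(w, 0.0) ** config.gamma
    strength = np.zeros(len(g.nodes))
    np.add.at(strength, g.eu, wg)
    np.add.at(strength, g.ev, wg)
    res = _expand(g, wg, strength, g.lp, g.edge_names.index(e), config.size_min, config.size_max)
    if res is None:
        return None
    members, score = res
    return SubNetwork(frozenset(g.nodes[i] for i in members), score, np.nan, e)


def find_modules(network: nx.Graph, config: SearchConfig | None = None) -> list[SubNetwork]:
    """Discover significant sub-networks.

    Expands the top ``max_seeds`` edges by weight, scores the resulting
    candidate modules against ``n_null`` permutation replicates (node
    adjusted p-values permuted over nodes, weights recomputed, identical
    seed-and-expand procedure), and keeps modules with add-one empirical
    p <= alpha, greedily deduplicated by Jaccard overlap in descending
    score order. Empirical p-values are stratified by module size
    (score distributions are strongly size-dependent): a candidate of
    size s is compared with each replicate's best score among
    expansions of size s +/- 2; replicates that never produced an
    expansion in that window contribute no exceedance.
    """
    config = config or SearchConfig()
    if network.number_of_edges() < config.size_min - 1:
        raise ValueError("network has fewer edges than size_min - 1")
    g = _ArrayGraph(network)
    observed = _run_search(g, g.lp, config)
    if not observed:
        return []

    rng = np.random.default_rng([config.seed, 5])
    by_size: list[dict[int, float]] = []
    for _ in range(config.n_null):
        if config.null_model == "rewire":
            g_null, lp_null = g.rewired(rng), g.lp
        else:
            g_null, lp_null = g, g.lp[rng.permutation(len(g.lp))]
        best: dict[int, float] = {}
        for members, score, _e in _run_search(g_null, lp_null, config):
            s = len(members)
            if score > best.get(s, -np.inf):
                best[s] = score
        by_size.append(best)

    accepted: list[SubNetwork] = []
    candidates = []
    for members, score, seed_edge in observed:
        s = len(members)
        half_w = max(2, int(np.ceil(0.2 * s)))
        window = range(max(config.size_min, s - half_w), min(config.size_max, s + half_w) + 1)
        exceed = populated = 0
        for rep in by_size:
            stat = max((rep[w] for w in window if w in rep), default=None)
            if stat is None:
                continue
            populated += 1
            if stat >= score - 1e-12:
                exceed += 1
        # conditional add-one estimator over replicates that realized the
        # stratum: sharp where the null populates it, conservative where
        # it does not (floor 1/(1+populated))
        emp_p = (1 + exceed) / (1 + populated)
        names = frozenset(g.nodes[i] for i in members)
        candidates.append(SubNetwork(names, score, emp_p, seed_edge))
    # overlapping candidates are variants of one discovery: deduplicate by
    # Jaccard in descending score order before significance testing
    distinct: list[SubNetwork] = []
    for cand in sorted(candidates, key=lambda m: (-m.score, m.size, sorted(m.members))):
        if all(
            len(cand.members & d.members) / len(cand.members | d.members)
            <= config.overlap_jaccard_max
            for d in distinct
        ):
            distinct.append(cand)
    # Holm step-down across the distinct discoveries: the search tests one
    # candidate per realized size stratum, so per-run family-wise error
    # must be controlled across them
    distinct.sort(key=lambda m: (m.empirical_p, -m.score, sorted(m.members)))
    m_tests = len(distinct)
    for i, cand in enumerate(distinct):
        if cand.empirical_p > config.alpha / (m_tests - i):
            break
        accepted.append(cand)
    accepted.sort(key=lambda m: (-m.score, m.size, sorted(m.members)))
    return accepted
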